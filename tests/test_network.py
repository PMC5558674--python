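import numpy as np
import pytest

from mirlasso.glasso import CovarianceInput, GraphicalLassoModel
from mirlasso.io import MIRNA, MRNA
from mirlasso.network import (
    InteractionNetwork, bipartite_view, build_network, extract_subnetwork,
    multi_target_genes, rank_hubs,
)


def random_net(rng, n_mir=5, n_mrna=12, p=0.25):
    node_class = {f"m{i}": MIRNA for i in range(n_mir)}
    node_class.update({f"g{i}": MRNA for i in range(n_mrna)})
    nodes = list(node_class)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], rng.random()))
    return InteractionNetwork.from_edges(node_class, edges)


class TestBuildNetwork:
    def _fit(self, rho=0.15, seed=0, m=6):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((m, m))
        X = rng.standard_normal((200, m)) @ A
        S = np.corrcoef(X.T)
        classes = [MIRNA if i < m // 2 else MRNA for i in range(m)]
        cov = CovarianceInput(S, [f"f{i}" for i in range(m)], classes, n=200)
        return GraphicalLassoModel(cov, rho=rho).fit()

    def test_diagonal_theta_means_no_edges(self):
        res = self._fit(rho=1.5)
        assert build_network(res).n_edges == 0

    def test_edge_count_matches_brute_force_scan(self):
        res = self._fit(rho=0.05)
        eps = 1e-8
        net = build_network(res, edge_eps=eps)
        upper = res.theta[np.triu_indices(res.m, k=1)]
        assert net.n_edges == int(np.sum(np.abs(upper) > eps))

    def test_edge_count_nonincreasing_in_eps(self):
        res = self._fit(rho=0.05)
        counts = [build_network(res, edge_eps=e).n_edges for e in (1e-10, 1e-4, 1e-1)]
        assert counts == sorted(counts, reverse=True)

    def test_nonconverged_estimate_requires_force(self):
        res = self._fit()
        res.converged = False
        with pytest.raises(ValueError, match="converge"):
            build_network(res)
        assert build_network(res, force=True).n_edges >= 0

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            InteractionNetwork.from_edges({"a": MIRNA}, [("a", "a", 1.0)])


class TestBipartiteView:
    def test_same_class_edges_dropped_nodes_kept(self):
        net = InteractionNetwork.from_edges(
            {"m1": MIRNA, "m2": MIRNA, "g1": MRNA},
            [("m1", "m2", 1.0), ("m1", "g1", 1.0)],
        )
        bip = bipartite_view(net)
        assert bip.edge_set() == {frozenset(("m1", "g1"))}
        assert set(bip.nodes) == {"m1", "m2", "g1"}

    def test_only_same_class_edges_yields_empty(self):
        net = InteractionNetwork.from_edges(
            {"m1": MIRNA, "m2": MIRNA}, [("m1", "m2", 1.0)]
        )
        assert bipartite_view(net).n_edges == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_retained_count_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng)
        cls = net.node_class
        same = sum(1 for u, v in net.edges if cls[u] == cls[v])
        bip = bipartite_view(net)
        assert bip.n_edges == net.n_edges - same
        assert bipartite_view(bip).edge_set() == bip.edge_set()


class TestRankHubs:
    def _star_net(self, degrees):
        node_class = {}
        edges = []
        for mi, (m, d) in enumerate(degrees.items()):
            node_class[m] = MIRNA
            for k in range(d):
                g = f"g{mi}_{k}"
                node_class[g] = MRNA
                edges.append((m, g, 1.0))
        return InteractionNetwork.from_edges(node_class, edges)

    def test_sorted_and_zero_degree_excluded(self):
        net = self._star_net({"a": 5, "b": 3, "c": 0})
        rk = rank_hubs(net, top_k=20)
        assert rk.ranking == [("a", 5), ("b", 3)]

    def test_lexicographic_tiebreak(self):
        net = self._star_net({"b": 5, "a": 5})
        assert [m for m, _ in rank_hubs(net).ranking] == ["a", "b"]

    def test_truncation_to_top_k(self):
        net = self._star_net({f"m{i}": i + 1 for i in range(10)})
        assert len(rank_hubs(net, top_k=3).ranking) == 3

    def test_invalid_top_k(self):
        with pytest.raises(ValueError):
            rank_hubs(self._star_net({"a": 1}), top_k=0)

    def test_degrees_count_mrna_neighbours_only(self):
        net = InteractionNetwork.from_edges(
            {"m1": MIRNA, "m2": MIRNA, "g1": MRNA},
            [("m1", "m2", 1.0), ("m1", "g1", 1.0)],
        )
        assert rank_hubs(net).ranking == [("m1", 1)]


class TestMultiTargetGenes:
    def test_boundary_inclusion_at_min(self):
        net = InteractionNetwork.from_edges(
            {"m1": MIRNA, "m2": MIRNA, "m3": MIRNA, "g": MRNA, "h": MRNA},
            [("m1", "g", 1), ("m2", "g", 1), ("m3", "g", 1),
             ("m1", "h", 1), ("m2", "h", 1)],
        )
        out = multi_target_genes(net, min_mirnas=3)
        assert out == [("g", ["m1", "m2", "m3"])]

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_degree_filter(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_net(rng)
        bip = bipartite_view(net)
        out = dict(multi_target_genes(bip, min_mirnas=2))
        g = bip.graph
        for node, cls in g.nodes(data="cls"):
            if cls != MRNA:
                continue
            mirs = {nb for nb in g.neighbors(node) if g.nodes[nb]["cls"] == MIRNA}
            if len(mirs) >= 2:
                assert set(out[node]) == mirs
            else:
                assert node not in out

    def test_invalid_min(self):
        net = InteractionNetwork.from_edges({"g": MRNA}, [])
        with pytest.raises(ValueError):
            multi_target_genes(net, min_mirnas=0)


class TestExtractSubnetwork:
    def test_isolated_mirna_gives_singleton(self):
        net = InteractionNetwork.from_edges({"m1": MIRNA, "g1": MRNA}, [])
        sub = extract_subnetwork(net, ["m1"])
        assert sub.nodes == ["m1"] and sub.n_edges == 0

    def test_star_extraction(self):
        net = InteractionNetwork.from_edges(
            {"m1": MIRNA, "g1": MRNA, "g2": MRNA, "g3": MRNA, "g4": MRNA},
            [("m1", "g1", 1), ("m1", "g2", 1), ("m1", "g3", 1)],
        )
        sub = extract_subnetwork(net, ["m1"])
        assert len(sub.nodes) == 4 and sub.n_edges == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_union_property(self, seed):
        rng = np.random.default_rng(200 + seed)
        bip = bipartite_view(random_net(rng))
        mirs = bip.mirnas()[:2]
        joint = extract_subnetwork(bip, mirs).edge_set()
        union = (extract_subnetwork(bip, [mirs[0]]).edge_set()
                 | extract_subnetwork(bip, [mirs[1]]).edge_set())
        assert joint == union

    def test_unknown_mirna_named(self):
        net = InteractionNetwork.from_edges({"m1": MIRNA}, [])
        with pytest.raises(ValueError, match="nope"):
            extract_subnetwork(net, ["nope"])


@pytest.mark.parametrize("seed", range(10))
def test_handshake_identity(seed):
    rng = np.random.default_rng(300 + seed)
    bip = bipartite_view(random_net(rng))
    g = bip.graph
    mir_deg = sum(d for n, d in g.degree if g.nodes[n]["cls"] == MIRNA)
    mrna_deg = sum(d for n, d in g.degree if g.nodes[n]["cls"] == MRNA)
    assert mir_deg == mrna_deg == bip.n_edges
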