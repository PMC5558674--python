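"""Interaction-network construction, bipartite view, hub ranking and queries.

A nonzero off-diagonal entry of the estimated precision matrix is an edge
(conditional dependence).  The full network keeps miRNA-miRNA and mRNA-mRNA
edges, but rankings and reports work on the bipartite view: only edges
joining a miRNA to an mRNA.  Hub miRNAs are ranked by degree (number of
connected mRNAs); ties break lexicographically so outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import FEATURE_CLASSES, MIRNA, MRNA


@dataclass
class InteractionNetwork:
    """Undirected graph over features, with class labels and |theta| weights."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, node_class: dict[str, str],
                   edges: list[tuple[str, str, float]]) -> "InteractionNetwork":
        g = nx.Graph()
        for node, c in node_class.items():
            if c not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {c!r} for node {node!r}")
            g.add_node(node, cls=c)
        for a, b, w in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in g or b not in g:
                raise ValueError(f"edge endpoint not in node set: {(a, b)}")
            g.add_edge(a, b, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def node_class(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="cls"))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def mirnas(self) -> list[str]:
        return [n for n, c in self.graph.nodes(data="cls") if c == MIRNA]

    def mrnas(self) -> list[str]:
        return [n for n, c in self.graph.nodes(data="cls") if c == MRNA]

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class HubRanking:
    """miRNAs ordered by bipartite degree (descending, lexicographic ties)."""

    ranking: list[tuple[str, int]]
    top_k: int

    def __post_init__(self) -> None:
        degs = [d for _, d in self.ranking]
        if any(d1 < d2 for d1, d2 in zip(degs, degs[1:])):
            raise ValueError("hub ranking degrees must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["mirna", "degree"])


def build_network(estimate, edge_eps: float = 1e-8, force: bool = False) -> InteractionNetwork:
    """Turn a fitted precision estimate into the full interaction network.

    Nodes are all retained features; edges are pairs with |theta_ab| >
    edge_eps.  A non-converged estimate is refused unless ``force`` is set.
    """
    if not estimate.converged and not force:
        raise ValueError(
            "estimate did not converge; refit with more iterations or pass force=True"
        )
    node_class = dict(zip(estimate.feature_ids, estimate.feature_class))
    return InteractionNetwork.from_edges(node_class, estimate.edges(eps=edge_eps))


def bipartite_view(net: InteractionNetwork) -> InteractionNetwork:
    """Drop same-class edges, keeping only miRNA-mRNA edges (idempotent)."""
    g = net.graph
    keep = [
        (u, v, d.get("weight", 1.0))
        for u, v, d in g.edges(data=True)
        if g.nodes[u]["cls"] != g.nodes[v]["cls"]
    ]
    return InteractionNetwork.from_edges(net.node_class, keep)


def _bipartite_degrees(net: InteractionNetwork) -> dict[str, int]:
    """mRNA-neighbor count per miRNA, counting only cross-class edges."""
    g = net.graph
    return {
        n: sum(1 for nb in g.neighbors(n) if g.nodes[nb]["cls"] == MRNA)
        for n, c in g.nodes(data="cls")
        if c == MIRNA
    }


def rank_hubs(net: InteractionNetwork, top_k: int = 20) -> HubRanking:
    """Rank miRNAs by number of connected mRNAs, truncated to the top_k.

    Degree-0 miRNAs are excluded; equal degrees order lexicographically by
    miRNA ID.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    degs = _bipartite_degrees(net)
    ranked = sorted(
        ((m, d) for m, d in degs.items() if d > 0),
        key=lambda md: (-md[1], md[0]),
    )
    return HubRanking(ranking=ranked[:top_k], top_k=top_k)


def multi_target_genes(net: InteractionNetwork, min_mirnas: int = 3
                       ) -> list[tuple[str, list[str]]]:
    """mRNAs connected to at least ``min_mirnas`` miRNAs, with their miRNAs.

    Sorted by miRNA count descending, then lexicographically by mRNA ID;
    each neighbour list is sorted.
    """
    if min_mirnas < 1:
        raise ValueError(f"min_mirnas must be >= 1, got {min_mirnas}")
    g = net.graph
    out = []
    for n, c in g.nodes(data="cls"):
        if c != MRNA:
            continue
        mirs = sorted(nb for nb in g.neighbors(n) if g.nodes[nb]["cls"] == MIRNA)
        if len(mirs) >= min_mirnas:
            out.append((n, mirs))
    out.sort(key=lambda item: (-len(item[1]), item[0]))
    return out


def extract_subnetwork(net: InteractionNetwork, mirna_ids: list[str]) -> InteractionNetwork:
    """Induced bipartite subgraph on the given miRNAs and their mRNA neighbours."""
    g = net.graph
    unknown = [m for m in mirna_ids if m not in g]
    if unknown:
        raise ValueError(f"unknown miRNA IDs: {unknown}")
    not_mirna = [m for m in mirna_ids if g.nodes[m]["cls"] != MIRNA]
    if not_mirna:
        raise ValueError(f"not miRNA nodes: {not_mirna}")
    mir_set = set(mirna_ids)
    nodes = set(mirna_ids)
    edges = []
    for m in mirna_ids:
        for nb in g.neighbors(m):
            if g.nodes[nb]["cls"] == MRNA:
                nodes.add(nb)
                edges.append((m, nb, g.edges[m, nb].get("weight", 1.0)))
    node_class = {n: g.nodes[n]["cls"] for n in nodes}
    # dedupe (a target shared by two listed miRNAs contributes two distinct edges,
    # but the same (m, nb) pair must not repeat)
    seen = set()
    uniq = []
    for a, b, w in edges:
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            uniq.append((a, b, w))
    return InteractionNetwork.from_edges(node_class, uniq)
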