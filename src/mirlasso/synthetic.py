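"""Synthetic expression data with planted DE effects and a planted sparse precision.

The generator emulates the statistical structure the pipeline assumes: two
patient groups, a subset of differentially expressed features, and a joint
Gaussian dependence network over miRNAs and mRNAs in which selected hub
miRNAs are conditionally dependent on planted target mRNAs.  Latent values
live on a log2-expression-like scale; ``noise='nb_counts'`` turns them into
negative-binomial read counts (fixed dispersion 0.1) so the count-based
fold-change gate behaves as it would on sequencing data.

All randomness flows through one numpy ``Generator(PCG64(seed))``, so a
fixed seed reproduces byte-identical data across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, MIRNA, MRNA

#: minimum eigenvalue enforced on the planted precision matrix
MIN_EIGENVALUE = 0.1

#: negative-binomial dispersion for count emission (var = m + 0.1 m^2)
NB_DISPERSION = 0.1

NOISE_MODELS = ("gaussian", "nb_counts")
DE_MODES = ("connected", "disjoint", "random", "none")


def mirna_id(i: int) -> str:
    return f"mir-{i:03d}"


def mrna_id(i: int) -> str:
    return f"gene-{i:04d}"


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``de_signs`` maps planted DE feature IDs to +1/-1 (up/down in group A);
    the realized log2 effect is sign * de_effect_log2 chosen at sampling
    time and recorded in ``de_features`` afterwards.
    """

    precision_true: np.ndarray
    feature_ids: list[str]
    feature_class: list[str]
    bipartite_edges_true: set[frozenset]
    hub_degrees_true: dict[str, int]
    de_signs: dict[str, float]
    seed: int
    de_features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        np.linalg.cholesky(self.precision_true)  # raises unless SPD
        support = set()
        m = self.precision_true.shape[0]
        for i in range(m):
            for j in range(i + 1, m):
                if self.precision_true[i, j] != 0.0:
                    support.add(frozenset((self.feature_ids[i], self.feature_ids[j])))
        if not self.bipartite_edges_true <= support:
            raise ValueError("planted bipartite edges must lie in the precision support")

    @property
    def m(self) -> int:
        return self.precision_true.shape[0]

    def mirna_ids(self) -> list[str]:
        return [f for f, c in zip(self.feature_ids, self.feature_class) if c == MIRNA]

    def mrna_ids(self) -> list[str]:
        return [f for f, c in zip(self.feature_ids, self.feature_class) if c == MRNA]


def make_precision(
    n_mirna: int,
    n_mrna: int,
    hubs: list[tuple[int, int]],
    offdiag_value: float = 0.25,
    seed: int = 0,
    de_mode: str = "connected",
    n_de: int | None = None,
) -> SyntheticTruth:
    """Build a planted sparse joint precision matrix with hub miRNAs.

    ``hubs`` lists (miRNA index, degree) pairs; each hub gets ``degree``
    distinct mRNA partners (sampled without replacement, seeded) with
    precision entries of magnitude ``offdiag_value`` and random sign.  The
    diagonal starts at 1 and is inflated by the smallest delta >= 0 that
    keeps the minimum eigenvalue at or above 0.1.

    ``de_mode`` selects which features carry DE effects when sampling:
    ``connected`` (every feature incident to a planted edge — the default,
    so the DE gate passes the network features through), ``disjoint``
    (an equally sized set of unconnected features, for testing the gate),
    ``random`` (``n_de`` features drawn from all classes, for null-network
    scenarios), or ``none``.
    """
    if de_mode not in DE_MODES:
        raise ValueError(f"de_mode must be one of {DE_MODES}")
    rng = np.random.default_rng(seed)
    m = n_mirna + n_mrna
    ids = [mirna_id(i) for i in range(n_mirna)] + [mrna_id(i) for i in range(n_mrna)]
    cls = [MIRNA] * n_mirna + [MRNA] * n_mrna
    theta = np.eye(m)
    edges: set[frozenset] = set()
    hub_degrees: dict[str, int] = {}
    for hub_idx, degree in hubs:
        if not 0 <= hub_idx < n_mirna:
            raise ValueError(f"hub miRNA index {hub_idx} out of range")
        if degree > n_mrna:
            raise ValueError(f"hub degree {degree} exceeds number of mRNAs {n_mrna}")
        targets = rng.choice(n_mrna, size=degree, replace=False)
        for t in targets:
            j = n_mirna + int(t)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            theta[hub_idx, j] = sign * offdiag_value
            theta[j, hub_idx] = sign * offdiag_value
            edges.add(frozenset((ids[hub_idx], ids[j])))
        hub_degrees[ids[hub_idx]] = int(degree)
    eigmin = float(np.linalg.eigvalsh(theta)[0])
    delta = max(0.0, MIN_EIGENVALUE - eigmin)
    if delta > 0.0:
        theta = theta + delta * np.eye(m)

    connected = sorted({f for e in edges for f in e}, key=ids.index)
    if de_mode == "connected":
        de_ids = connected
    elif de_mode == "disjoint":
        pool = [f for f in ids if f not in set(connected)]
        k = min(len(connected), len(pool))
        de_ids = list(rng.choice(pool, size=k, replace=False)) if k else []
    elif de_mode == "random":
        k = min(m, int(n_de) if n_de is not None else max(1, m // 10))
        # draw from each class so both matrices keep DE features
        mir_pool = ids[:n_mirna]
        mrna_pool = ids[n_mirna:]
        k_mir = max(1, round(k * n_mirna / m)) if n_mirna else 0
        k_mir = min(k_mir, n_mirna)
        k_mrna = min(k - k_mir, n_mrna)
        de_ids = list(rng.choice(mir_pool, size=k_mir, replace=False)) + list(
            rng.choice(mrna_pool, size=k_mrna, replace=False)
        )
    else:
        de_ids = []
    de_signs = {f: (1.0 if rng.random() < 0.5 else -1.0) for f in de_ids}
    return SyntheticTruth(
        precision_true=theta, feature_ids=ids, feature_class=cls,
        bipartite_edges_true=edges, hub_degrees_true=hub_degrees,
        de_signs=de_signs, seed=int(seed),
    )


def sample_expression(
    truth: SyntheticTruth,
    n_per_group: int,
    de_effect_log2: float = 0.0,
    noise: str = "gaussian",
    seed: int = 0,
    baseline_log2: float = 5.0,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Draw a two-group dataset from the planted model.

    Latent rows are N(mu_g, theta_true^-1); group A's mean is shifted by
    sign * de_effect_log2 on the planted DE features.  ``gaussian`` emits
    the latent values directly (log2-expression scale); ``nb_counts`` emits
    negative-binomial counts with mean 2^latent and dispersion 0.1.  The
    clinical table assigns survival_days 100 (group A) / 700 (group B),
    ER-negative/positive and stage III/I, so every grouping rule recovers
    the two groups.  Realized effects are recorded in ``truth.de_features``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if noise not in NOISE_MODELS:
        raise ValueError(f"noise must be one of {NOISE_MODELS}")
    rng = np.random.default_rng(seed)
    m = truth.m
    sigma = np.linalg.inv(truth.precision_true)
    L = np.linalg.cholesky(sigma)
    n = 2 * n_per_group

    mu = np.full((n, m), float(baseline_log2))
    for fid, sign in truth.de_signs.items():
        j = truth.feature_ids.index(fid)
        mu[:n_per_group, j] += sign * de_effect_log2
    truth.de_features = {
        f: s * de_effect_log2 for f, s in truth.de_signs.items()
    }

    latent = mu + rng.standard_normal((n, m)) @ L.T
    if noise == "gaussian":
        values = latent
    else:
        means = np.exp2(latent)
        r = 1.0 / NB_DISPERSION
        p = r / (r + means)
        values = rng.negative_binomial(r, p).astype(float)

    sample_ids = [f"sample-{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=truth.feature_ids),
        pd.Series(truth.feature_class, index=truth.feature_ids),
    )
    clin = pd.DataFrame(
        {
            "survival_days": [100.0] * n_per_group + [700.0] * n_per_group,
            "er_status": ["negative"] * n_per_group + ["positive"] * n_per_group,
            "stage": ["III"] * n_per_group + ["I"] * n_per_group,
        },
        index=pd.Index(sample_ids),
    )
    return expr, ClinicalTable(clin)


def split_by_class(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split an integrated matrix into its (miRNA, mRNA) blocks."""
    mir = [f for f in expr.feature_ids if expr.feature_class[f] == MIRNA]
    mr = [f for f in expr.feature_ids if expr.feature_class[f] == MRNA]
    return expr.subset_features(mir), expr.subset_features(mr)


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Write planted edges, DE effects and hub degrees as three TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = sorted(tuple(sorted(e)) for e in truth.bipartite_edges_true)
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
        out / "truth_edges.tsv", sep="\t", index=False
    )
    de = sorted(truth.de_features.items()) if truth.de_features else sorted(
        (f, s) for f, s in truth.de_signs.items()
    )
    pd.DataFrame(de, columns=["feature_id", "log2_effect"]).to_csv(
        out / "truth_de.tsv", sep="\t", index=False
    )
    hubs = sorted(truth.hub_degrees_true.items(), key=lambda kv: (-kv[1], kv[0]))
    pd.DataFrame(hubs, columns=["mirna", "degree"]).to_csv(
        out / "truth_hubs.tsv", sep="\t", index=False
    )
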