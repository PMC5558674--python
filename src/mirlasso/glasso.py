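"""Sparse Gaussian graphical model estimation by the graphical lasso.

The estimator maximizes the L1-penalized Gaussian log-likelihood

    log det(theta) - tr(S theta) - rho * ||theta||_1

over positive-definite precision matrices theta, where S is the empirical
(1/n) covariance of the integrated expression matrix Z and rho >= 0 controls
sparsity.  ||theta||_1 is the entrywise sum of absolute values; with the
default convention the diagonal is penalized too, which fixes the dual
covariance diagonal at W_ii = S_ii + rho.

The solver is the block coordinate descent of the graphical-lasso family:
cycle over columns of the dual covariance W, solve each column's lasso
subproblem by coordinate descent, and recover theta from the lasso
coefficients at convergence.  A nonzero off-diagonal theta_ab means features
a and b are conditionally dependent given all others — an edge in the
interaction network.

Usage follows the Model/Results convention::

    model = GraphicalLassoModel.from_expression(Z, rho=0.2)
    res = model.fit()
    print(res.summary())
    net = res.to_network()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .io import ExpressionMatrix, FEATURE_CLASSES, MIRNA, MRNA

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "log2p1")
SCALES = ("covariance", "correlation")

#: |theta_ab| above this counts as an edge (a hard zero is solver-dependent)
EDGE_EPS = 1e-8


class GlassoError(RuntimeError):
    """Numerical failure inside the graphical-lasso solver."""


@dataclass
class CovarianceInput:
    """Empirical covariance S with feature metadata, the solver's input.

    S is symmetrized on construction; a non-positive diagonal entry (constant
    feature) is rejected — constant features must be removed upstream.
    """

    S: np.ndarray
    feature_ids: list[str]
    feature_class: list[str]
    n: int
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"S must be square, got shape {S.shape}")
        if S.shape[0] != len(self.feature_ids):
            raise ValueError("feature_ids length does not match S")
        if len(self.feature_class) != len(self.feature_ids):
            raise ValueError("feature_class length does not match feature_ids")
        if np.max(np.abs(S - S.T), initial=0.0) > 1e-10 * max(1.0, np.abs(S).max()):
            raise ValueError("S is not symmetric within tolerance")
        self.S = 0.5 * (S + S.T)
        if np.any(np.diag(self.S) <= 0):
            bad = [self.feature_ids[i] for i in np.flatnonzero(np.diag(self.S) <= 0)]
            raise ValueError(f"non-positive variance for features {bad}; drop constants first")

    @property
    def m(self) -> int:
        return self.S.shape[0]


def empirical_covariance(
    Z: ExpressionMatrix,
    transform: str = "none",
    scale: str = "covariance",
    groups=None,
) -> CovarianceInput:
    """Compute the maximum-likelihood (1/n) covariance of Z.

    ``transform='log2p1'`` applies log2(x+1) first (counts on a bounded
    scale); ``scale='correlation'`` rescales S to unit diagonal so a single
    penalty rho acts uniformly across features.  Constant columns (after the
    transform) are removed and reported on the result; an all-constant
    matrix is an error.

    ``groups`` (optional, a :class:`~mirlasso.diffexpr.GroupAssignment` or a
    pair of sample-ID lists) switches to the pooled within-group covariance:
    each group is centred on its own mean before forming S.  This removes
    the between-group mean shift, which otherwise acts as a shared latent
    factor inflating apparent correlations among differentially expressed
    features.  Default (None) centres on the grand mean.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}")
    X = Z.to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples to form a covariance, got {n}")
    if transform == "log2p1":
        if X.min() <= -1.0:
            raise ValueError("log2p1 transform requires values > -1")
        X = np.log2(X + 1.0)
    keep = X.std(axis=0) > 0.0
    dropped = [f for f, k in zip(Z.feature_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all features are constant; no covariance to estimate")
    if dropped:
        logger.info("removed %d constant features before covariance", len(dropped))
    X = X[:, keep]
    ids = [f for f, k in zip(Z.feature_ids, keep) if k]
    cls = [Z.feature_class[f] for f in ids]
    if groups is None:
        Xc = X - X.mean(axis=0)
    else:
        if hasattr(groups, "group_a"):
            group_lists = [groups.group_a, groups.group_b]
        else:
            group_lists = [list(g) for g in groups]
        sample_pos = {s: i for i, s in enumerate(Z.sample_ids)}
        Xc = X.astype(float).copy()
        assigned = np.zeros(n, dtype=bool)
        for g in group_lists:
            idx = []
            for s in g:
                if s not in sample_pos:
                    raise ValueError(f"group sample {s!r} absent from expression matrix")
                idx.append(sample_pos[s])
            if len(idx) < 2:
                raise ValueError("each centring group needs >= 2 samples")
            if assigned[idx].any():
                raise ValueError("centring groups overlap")
            assigned[idx] = True
            Xc[idx] -= X[idx].mean(axis=0)
        rest = np.flatnonzero(~assigned)
        if rest.size:
            Xc[rest] -= X[rest].mean(axis=0)
    S = (Xc.T @ Xc) / n
    if scale == "correlation":
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        np.fill_diagonal(S, 1.0)
    return CovarianceInput(S=S, feature_ids=ids, feature_class=cls, n=n,
                           dropped_features=dropped)


def penalized_loglik(theta: np.ndarray, S: np.ndarray, rho: float,
                     penalize_diagonal: bool = True) -> float:
    """Value of log det(theta) - tr(S theta) - rho*||theta||_1 (the objective)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    pen = np.abs(theta).sum()
    if not penalize_diagonal:
        pen -= np.abs(np.diag(theta)).sum()
    return float(logdet - (S * theta).sum() - rho * pen)


@dataclass
class GraphicalLassoResults:
    """Fitted precision estimate with diagnostics (the fit() return value).

    Attributes
    ----------
    theta : ndarray
        Estimated sparse precision matrix (symmetric positive definite).
    W : ndarray
        Estimated covariance, the solver's dual variable (W ~ theta^-1).
    objective : float
        Penalized log-likelihood at theta.
    kkt_bound_violation : float
        max over off-diagonals of (|W_ij - S_ij| - rho), clipped at 0.
    kkt_active_residual : float
        max over edges of |W_ij - S_ij - rho*sign(theta_ij)|.
    duality_gap : float
        tr(S theta) + rho*||theta||_1 - m (zero at the optimum when
        theta^-1 is dual feasible).
    """

    theta: np.ndarray
    W: np.ndarray
    rho: float
    objective: float
    iterations: int
    converged: bool
    kkt_bound_violation: float
    kkt_active_residual: float
    duality_gap: float
    feature_ids: list[str]
    feature_class: list[str]
    n: int
    tol: float
    penalize_diagonal: bool = True
    _B: np.ndarray | None = None  # lasso coefficients, kept for warm starts

    @property
    def m(self) -> int:
        return self.theta.shape[0]

    @property
    def kkt_residual(self) -> float:
        return max(self.kkt_bound_violation, self.kkt_active_residual)

    def edges(self, eps: float = EDGE_EPS) -> list[tuple[str, str, float]]:
        """Feature pairs with |theta_ab| > eps, as (id_a, id_b, |theta_ab|)."""
        out = []
        m = self.m
        for i in range(m):
            for j in range(i + 1, m):
                w = abs(self.theta[i, j])
                if w > eps:
                    out.append((self.feature_ids[i], self.feature_ids[j], w))
        return out

    def n_edges(self, eps: float = EDGE_EPS) -> int:
        m = self.m
        upper = self.theta[np.triu_indices(m, k=1)]
        return int(np.count_nonzero(np.abs(upper) > eps))

    def theta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.feature_ids, columns=self.feature_ids)

    def to_network(self, edge_eps: float = EDGE_EPS, force: bool = False):
        from .network import build_network

        return build_network(self, edge_eps=edge_eps, force=force)

    def summary(self) -> str:
        """Human-readable fit summary in the statsmodels style."""
        n_mir = sum(c == MIRNA for c in self.feature_class)
        n_mrna = sum(c == MRNA for c in self.feature_class)
        edges = self.edges()
        cls = dict(zip(self.feature_ids, self.feature_class))
        kinds = {"miRNA-mRNA": 0, "miRNA-miRNA": 0, "mRNA-mRNA": 0}
        for a, b, _ in edges:
            ca, cb = cls[a], cls[b]
            if ca != cb:
                kinds["miRNA-mRNA"] += 1
            elif ca == MIRNA:
                kinds["miRNA-miRNA"] += 1
            else:
                kinds["mRNA-mRNA"] += 1
        lines = [
            "Graphical Lasso Results",
            "=" * 46,
            f"{'No. features:':<28}{self.m} ({n_mir} miRNA, {n_mrna} mRNA)",
            f"{'No. samples:':<28}{self.n}",
            f"{'Penalty rho:':<28}{self.rho:g}",
            f"{'Converged:':<28}{self.converged} ({self.iterations} sweeps)",
            f"{'Objective:':<28}{self.objective:.6g}",
            f"{'KKT bound violation:':<28}{self.kkt_bound_violation:.3g}",
            f"{'KKT active residual:':<28}{self.kkt_active_residual:.3g}",
            f"{'Duality gap:':<28}{self.duality_gap:.3g}",
            f"{'Edges (|theta|>1e-08):':<28}{len(edges)}",
            f"{'  miRNA-mRNA:':<28}{kinds['miRNA-mRNA']}",
            f"{'  miRNA-miRNA:':<28}{kinds['miRNA-miRNA']}",
            f"{'  mRNA-mRNA:':<28}{kinds['mRNA-mRNA']}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_precision(self, ax=None):
        """Heat map of the estimated precision matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        vmax = np.abs(self.theta - np.diag(np.diag(self.theta))).max() or 1.0
        im = ax.imshow(self.theta, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(f"Precision estimate (rho={self.rho:g})")
        ax.figure.colorbar(im, ax=ax, label=r"$\theta_{ab}$")
        return ax


class GraphicalLassoModel:
    """L1-penalized Gaussian precision model over an empirical covariance.

    Parameters
    ----------
    cov : CovarianceInput
        Empirical covariance with feature metadata (see
        :func:`empirical_covariance`).
    rho : float
        Nonnegative sparsity penalty.  Larger rho gives fewer edges; rho at
        or above the largest off-diagonal |S_ij| gives a diagonal theta.
    penalize_diagonal : bool
        Default True (entrywise penalty, dual diagonal W_ii = S_ii + rho).
        False reproduces the convention of solvers that leave the diagonal
        unpenalized, useful for cross-checks.
    """

    def __init__(self, cov: CovarianceInput, rho: float = 2.0,
                 penalize_diagonal: bool = True) -> None:
        if rho < 0:
            raise ValueError(f"rho must be nonnegative, got {rho}")
        self.cov = cov
        self.rho = float(rho)
        self.penalize_diagonal = bool(penalize_diagonal)

    @classmethod
    def from_expression(cls, Z: ExpressionMatrix, rho: float = 2.0,
                        transform: str = "log2p1", scale: str = "correlation",
                        groups=None,
                        penalize_diagonal: bool = True) -> "GraphicalLassoModel":
        """Build the model straight from an integrated expression matrix."""
        return cls(empirical_covariance(Z, transform=transform, scale=scale,
                                        groups=groups),
                   rho=rho, penalize_diagonal=penalize_diagonal)

    def fit(self, tol: float = 1e-4, max_iter: int = 100,
            inner_tol: float = 1e-6, inner_max_iter: int = 1000,
            warm_start: GraphicalLassoResults | None = None) -> GraphicalLassoResults:
        """Run block coordinate descent and return a results object.

        ``tol`` is relative: convergence when the mean absolute change of W
        off-diagonals per sweep drops below tol * mean|S off-diagonal|.
        Reaching ``max_iter`` returns a results object with
        ``converged=False`` (network construction then requires ``force``).
        """
        S = self.cov.S
        m = self.cov.m
        rho = self.rho
        if rho == 0.0 and np.linalg.matrix_rank(S) < m:
            raise GlassoError("rho=0 requires a nonsingular empirical covariance")
        if warm_start is not None and warm_start._B is not None and warm_start.m == m:
            W = warm_start.W.copy()
            B = warm_start._B.copy()
            np.fill_diagonal(W, np.diag(S) + (rho if self.penalize_diagonal else 0.0))
        else:
            W = S.copy()
            if self.penalize_diagonal:
                W[np.diag_indices(m)] += rho
            B = np.zeros((m, m))
        sweeps, converged = _solver.glasso_sweeps(
            S, rho, tol, max_iter, inner_tol, inner_max_iter, W, B
        )
        theta, ok = _solver.recover_theta(W, B)
        if not ok:
            raise GlassoError(
                "non-positive-definite iterate while recovering theta "
                f"(m={m}, rho={rho}); the input covariance may be degenerate"
            )
        eigmin = np.linalg.eigvalsh(theta)[0]
        if eigmin <= 0:
            raise GlassoError(f"recovered theta not positive definite (min eig {eigmin:g})")

        R = W - S
        off = ~np.eye(m, dtype=bool)
        bound_violation = float(max(0.0, (np.abs(R)[off].max(initial=0.0) - rho))) if m > 1 else 0.0
        active = off & (np.abs(theta) > EDGE_EPS)
        if active.any():
            active_res = float(np.abs(R[active] - rho * np.sign(theta[active])).max())
        else:
            active_res = 0.0
        gap = float((S * theta).sum() + rho * (
            np.abs(theta).sum() - (0.0 if self.penalize_diagonal else np.abs(np.diag(theta)).sum())
        ) - m)
        obj = penalized_loglik(theta, S, rho, self.penalize_diagonal)
        if not converged:
            logger.warning("graphical lasso did not converge in %d sweeps", max_iter)
        return GraphicalLassoResults(
            theta=theta, W=W, rho=rho, objective=obj, iterations=sweeps,
            converged=bool(converged), kkt_bound_violation=bound_violation,
            kkt_active_residual=active_res, duality_gap=gap,
            feature_ids=list(self.cov.feature_ids),
            feature_class=list(self.cov.feature_class),
            n=self.cov.n, tol=tol, penalize_diagonal=self.penalize_diagonal,
            _B=B,
        )


def graphical_lasso(cov: CovarianceInput, rho: float = 2.0, tol: float = 1e-4,
                    max_iter: int = 100, **fit_kwargs) -> GraphicalLassoResults:
    """Functional wrapper: fit a GraphicalLassoModel in one call."""
    return GraphicalLassoModel(cov, rho=rho).fit(tol=tol, max_iter=max_iter, **fit_kwargs)


def regularization_path(cov: CovarianceInput, rhos, tol: float = 1e-4,
                        max_iter: int = 100, penalize_diagonal: bool = True,
                        **fit_kwargs) -> list[GraphicalLassoResults]:
    """Fit along a penalty path, warm-starting each rho from the previous fit.

    ``rhos`` are sorted decreasing internally; the returned list follows that
    order (each result carries its rho).  Full-path edge-count monotonicity
    is not guaranteed and not asserted, but the warm starts make the path
    much cheaper than cold fits.
    """
    rhos = sorted(float(r) for r in rhos)
    if not rhos:
        return []
    if rhos[0] <= 0:
        raise ValueError("path rhos must be strictly positive")
    results: list[GraphicalLassoResults] = []
    prev: GraphicalLassoResults | None = None
    for rho in reversed(rhos):  # largest first
        model = GraphicalLassoModel(cov, rho=rho, penalize_diagonal=penalize_diagonal)
        prev = model.fit(tol=tol, max_iter=max_iter, warm_start=prev, **fit_kwargs)
        results.append(prev)
    return results
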