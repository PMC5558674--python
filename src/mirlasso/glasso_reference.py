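"""Independent proximal-gradient reference solver for the penalized likelihood.

This is a generic first-order convex optimizer (FISTA with backtracking and
restarts) applied directly to

    minimize  -log det(theta) + tr(S theta) + rho * ||theta||_1

over symmetric positive-definite theta.  It shares no code with the block
coordinate descent solver in :mod:`mirlasso.glasso` and exists purely as a
validation oracle: slow, simple, and checked against first-order optimality
conditions before returning.  Intended for small problems (m up to a few
dozen).
"""

from __future__ import annotations

import numpy as np


def _smooth(theta: np.ndarray, S: np.ndarray) -> float:
    # Cholesky doubles as the PD test: slogdet alone would miss matrices
    # with an even number of negative eigenvalues (det > 0 but not PD)
    try:
        C = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(C))))
    return float(-logdet + (S * theta).sum())


def _soft(X: np.ndarray, t: float, penalize_diagonal: bool) -> np.ndarray:
    Z = np.sign(X) * np.maximum(np.abs(X) - t, 0.0)
    if not penalize_diagonal:
        np.fill_diagonal(Z, np.diag(X))
    return Z


def _is_pd(theta: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(theta)
        return True
    except np.linalg.LinAlgError:
        return False


def optimality_residual(theta: np.ndarray, S: np.ndarray, rho: float,
                        penalize_diagonal: bool = True,
                        active_eps: float = 1e-10) -> float:
    """Max-norm violation of the subgradient stationarity condition at theta."""
    G = np.linalg.inv(theta) - S  # should lie in rho * subgradient(||theta||_1)
    m = S.shape[0]
    resid = 0.0
    for i in range(m):
        for j in range(m):
            if i == j and not penalize_diagonal:
                r = abs(G[i, j])
            elif abs(theta[i, j]) > active_eps:
                r = abs(G[i, j] - rho * np.sign(theta[i, j]))
            else:
                r = max(0.0, abs(G[i, j]) - rho)
            resid = max(resid, r)
    return resid


def reference_graphical_lasso(S: np.ndarray, rho: float,
                              penalize_diagonal: bool = True,
                              opt_tol: float = 1e-8,
                              max_iter: int = 200_000) -> np.ndarray:
    """Solve the penalized-likelihood problem by FISTA; return theta.

    Stops when the stationarity residual (checked every 50 iterations) falls
    below ``opt_tol``.  Raises if the residual target is not reached within
    ``max_iter`` iterations.
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    theta = np.diag(1.0 / (np.diag(S) + (rho if penalize_diagonal else 0.0) + 1e-12))
    y = theta.copy()
    t = 1.0
    L = max(1.0, float(np.abs(S).max()))
    for it in range(1, max_iter + 1):
        fy = _smooth(y, S)
        if not np.isfinite(fy):
            # extrapolation left the PD cone: restart momentum
            y = theta.copy()
            t = 1.0
            fy = _smooth(y, S)
        grad = S - np.linalg.inv(y)
        while True:
            z = _soft(y - grad / L, rho / L, penalize_diagonal)
            z = 0.5 * (z + z.T)
            diff = z - y
            fz = _smooth(z, S)
            if np.isfinite(fz) and fz <= fy + (grad * diff).sum() + 0.5 * L * (diff ** 2).sum() + 1e-14:
                break
            L *= 2.0
            if L > 1e18:
                raise RuntimeError("reference solver backtracking failed")
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = z + ((t - 1.0) / t_new) * (z - theta)
        theta = z
        t = t_new
        L = max(L * 0.9, 1e-8)  # gentle step-size recovery
        if it % 50 == 0 and _is_pd(theta):
            if optimality_residual(theta, S, rho, penalize_diagonal) < opt_tol:
                return theta
    resid = optimality_residual(theta, S, rho, penalize_diagonal)
    if resid < 10 * opt_tol:
        return theta
    raise RuntimeError(
        f"reference solver did not reach optimality (residual {resid:g} after {max_iter} iters)"
    )
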