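"""Numba kernels for the graphical-lasso block coordinate descent.

The outer loop cycles over columns of the working covariance W, solving each
column's lasso subproblem by cyclic coordinate descent with soft-thresholding
(cycling order = input order, no randomization, so runs are bit-reproducible
for fixed input and tolerances).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lasso_cd(V, s, beta, rho, tol, max_iter):
    """Minimize 0.5 b'Vb - s'b + rho*||b||_1 in place by cyclic CD.

    ``beta`` is updated in place (warm start in, solution out).  Returns the
    number of passes used.
    """
    p = V.shape[0]
    q = np.zeros(p)
    for i in range(p):
        acc = 0.0
        for k in range(p):
            acc += V[i, k] * beta[k]
        q[i] = acc
    passes = 0
    for _ in range(max_iter):
        passes += 1
        max_delta = 0.0
        for k in range(p):
            old = beta[k]
            gk = s[k] - (q[k] - V[k, k] * old)
            if gk > rho:
                new = (gk - rho) / V[k, k]
            elif gk < -rho:
                new = (gk + rho) / V[k, k]
            else:
                new = 0.0
            if new != old:
                d = new - old
                for i in range(p):
                    q[i] += V[i, k] * d
                beta[k] = new
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            break
    return passes


@njit(cache=True)
def glasso_sweeps(S, rho, tol, max_sweeps, inner_tol, inner_max_iter, W, B):
    """Run block coordinate descent sweeps on W (and lasso coefficients B).

    W and B are updated in place (callers pass warm starts or fresh arrays).
    Convergence: mean absolute change of W off-diagonals per sweep below
    tol * mean|S off-diagonal| (tol itself when S is diagonal).

    Returns (sweeps_used, converged).
    """
    m = S.shape[0]
    if m == 1:
        return 0, True
    denom = m * (m - 1)
    s_off = 0.0
    for i in range(m):
        for j in range(m):
            if i != j:
                s_off += abs(S[i, j])
    mean_off = s_off / denom
    thresh = tol * mean_off if mean_off > 0.0 else tol

    V = np.empty((m - 1, m - 1))
    s12 = np.empty(m - 1)
    beta = np.empty(m - 1)
    wnew = np.empty(m - 1)
    sweeps = 0
    converged = False
    for _ in range(max_sweeps):
        sweeps += 1
        total = 0.0
        for j in range(m):
            r = 0
            for a in range(m):
                if a == j:
                    continue
                s12[r] = S[a, j]
                beta[r] = B[a, j]
                c = 0
                for b in range(m):
                    if b == j:
                        continue
                    V[r, c] = W[a, b]
                    c += 1
                r += 1
            lasso_cd(V, s12, beta, rho, inner_tol, inner_max_iter)
            for rr in range(m - 1):
                acc = 0.0
                for cc in range(m - 1):
                    acc += V[rr, cc] * beta[cc]
                wnew[rr] = acc
            r = 0
            for a in range(m):
                if a == j:
                    continue
                total += abs(W[a, j] - wnew[r])
                W[a, j] = wnew[r]
                W[j, a] = wnew[r]
                B[a, j] = beta[r]
                r += 1
        if total / denom < thresh:
            converged = True
            break
    return sweeps, converged


@njit(cache=True)
def recover_theta(W, B):
    """Invert the bordered W blockwise to get theta from the lasso coefficients.

    theta_jj = 1/(W_jj - w12'beta), theta_.j = -beta * theta_jj, then
    symmetrized.  Returns (theta, ok); ok is False when a pivot is
    non-positive (numerical loss of positive definiteness).
    """
    m = W.shape[0]
    theta = np.zeros((m, m))
    for j in range(m):
        dot = 0.0
        for a in range(m):
            if a != j:
                dot += W[a, j] * B[a, j]
        pivot = W[j, j] - dot
        if pivot <= 0.0:
            return theta, False
        tjj = 1.0 / pivot
        theta[j, j] = tjj
        for a in range(m):
            if a != j:
                theta[a, j] = -B[a, j] * tjj
    for i in range(m):
        for j in range(i + 1, m):
            v = 0.5 * (theta[i, j] + theta[j, i])
            theta[i, j] = v
            theta[j, i] = v
    return theta, True
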