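"""Numba kernels for the penalized estimators.

Two inner loops live here: the block coordinate descent for the
(weighted) graphical LASSO, and a plain LASSO coordinate descent used by
neighbor selection. Both operate in place on caller-provided state so
that warm starts across a regularization path or a bisection search are
cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_cd", "ns_lasso_all"]


@njit(cache=True)
def glasso_cd(S, Lam, W, B, thresh, max_iter, inner_max):
    """Block coordinate descent for min -logdet(T) + tr(S T) + ||Lam * T||_1.

    Parameters
    ----------
    S : (p, p) sample covariance (symmetric, positive diagonal).
    Lam : (p, p) element-wise penalty matrix, entries >= 0. Lam[j, j] is
        added to the working covariance diagonal (diagonal penalty); pass
        a zero diagonal to leave the diagonal unpenalized.
    W : (p, p) working covariance estimate, modified in place. For a cold
        start initialize to S with Lam's diagonal added; for a warm start
        pass the previous solution's working covariance.
    B : (p, p) regression coefficients, B[i, j] is the coefficient of
        variable i in the column-j subproblem (B[j, j] == 0). Modified in
        place; zeros for a cold start.
    thresh : outer convergence threshold on the mean absolute change of
        the off-diagonal working covariance per sweep.
    max_iter : maximum outer sweeps.
    inner_max : maximum coordinate sweeps per column subproblem.

    Returns
    -------
    (iterations, converged) with converged as 0/1 int.
    """
    p = S.shape[0]
    v = np.empty(p)
    n_off = p * (p - 1)
    it = 0
    converged = 0
    inner_thresh = thresh * 0.1
    for it in range(1, max_iter + 1):
        delta = 0.0
        for j in range(p):
            # v = W @ B[:, j]; B[j, j] is structurally zero
            for i in range(p):
                acc = 0.0
                for k in range(p):
                    acc += W[i, k] * B[k, j]
                v[i] = acc
            # coordinate descent on the column-j lasso subproblem
            for _ in range(inner_max):
                maxd = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    g = S[i, j] - v[i] + W[i, i] * B[i, j]
                    l = Lam[i, j]
                    if g > l:
                        bn = (g - l) / W[i, i]
                    elif g < -l:
                        bn = (g + l) / W[i, i]
                    else:
                        bn = 0.0
                    d = bn - B[i, j]
                    if d != 0.0:
                        B[i, j] = bn
                        for k in range(p):
                            v[k] += W[k, i] * d
                        ad = abs(d)
                        if ad > maxd:
                            maxd = ad
                if maxd < inner_thresh:
                    break
            for i in range(p):
                if i != j:
                    d = v[i] - W[i, j]
                    delta += abs(d)
                    W[i, j] = v[i]
                    W[j, i] = v[i]
        if n_off > 0 and delta / n_off < thresh:
            converged = 1
            break
        if n_off == 0:
            converged = 1
            break
    return it, converged


@njit(cache=True)
def glasso_theta(W, B):
    """Recover the precision matrix from the working covariance and
    per-column regression coefficients (standard back-substitution)."""
    p = W.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for i in range(p):
            dot += W[i, j] * B[i, j]
        tjj = 1.0 / (W[j, j] - dot)
        theta[j, j] = tjj
        for i in range(p):
            if i != j:
                theta[i, j] = -B[i, j] * tjj
    # symmetrize
    for i in range(p):
        for j in range(i + 1, p):
            m = 0.5 * (theta[i, j] + theta[j, i])
            theta[i, j] = m
            theta[j, i] = m
    return theta


@njit(cache=True)
def ns_lasso_all(X, lam, B, tol, max_iter):
    """One L1 regression per node: column j of X on all other columns.

    X must have centered columns with unit sum of squares. B[:, j] holds
    the coefficients for node j's regression (B[j, j] == 0), warm-startable.
    Penalty is 0.5 * ||x_j - X b||^2 + lam * ||b||_1, shared across nodes.
    """
    n, p = X.shape
    r = np.empty(n)
    for j in range(p):
        for t in range(n):
            acc = X[t, j]
            for k in range(p):
                acc -= X[t, k] * B[k, j]
            r[t] = acc
        for _ in range(max_iter):
            maxd = 0.0
            for i in range(p):
                if i == j:
                    continue
                g = B[i, j]
                for t in range(n):
                    g += X[t, i] * r[t]
                if g > lam:
                    bn = g - lam
                elif g < -lam:
                    bn = g + lam
                else:
                    bn = 0.0
                d = bn - B[i, j]
                if d != 0.0:
                    B[i, j] = bn
                    for t in range(n):
                        r[t] -= X[t, i] * d
                    ad = abs(d)
                    if ad > maxd:
                        maxd = ad
            if maxd < tol:
                break
    return B
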