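"""Independent reference implementations used only to verify the package.

The proximal-gradient (ISTA) minimizer below solves the same penalized
likelihood as the block coordinate descent solver but by an entirely
different algorithm, so agreement between the two certifies both the
objective and the optimizer.
"""

from __future__ import annotations

import numpy as np


def ista_glasso(
    S: np.ndarray,
    lam_mat: np.ndarray,
    max_iter: int = 20000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Proximal-gradient minimization of -logdet(T) + tr(ST) + ||lam_mat*T||_1.

    Backtracking line search keeps iterates positive definite. Intended
    for tiny p (<= 6); slow but independent of the production solver.
    """
    p = S.shape[0]
    theta = np.linalg.inv(S + np.diag(np.diag(lam_mat)) + 1e-3 * np.eye(p))
    theta = 0.5 * (theta + theta.T)

    def smooth(t):
        sign, logdet = np.linalg.slogdet(t)
        if sign <= 0:
            return np.inf
        return -logdet + np.trace(S @ t)

    def total(t):
        return smooth(t) + np.sum(lam_mat * np.abs(t))

    step = 1.0
    f_prev = total(theta)
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        while True:
            cand = theta - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * lam_mat, 0.0)
            cand = 0.5 * (cand + cand.T)
            fs = smooth(cand)
            if np.isfinite(fs):
                diff = cand - theta
                quad = smooth(theta) + np.sum(grad * diff) + np.sum(diff**2) / (2 * step)
                if fs <= quad + 1e-12:
                    break
            step *= 0.5
            if step < 1e-12:
                return theta
        theta = cand
        f = total(theta)
        if abs(f_prev - f) < tol * max(1.0, abs(f)):
            break
        f_prev = f
        step *= 1.1
    return theta
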