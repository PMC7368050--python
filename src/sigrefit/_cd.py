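"""Cyclic coordinate descent for non-negative penalized least squares.

Solves, in Gram form with per-coefficient penalty factors c_k and elastic-net
mixing gamma,

    min_{w >= 0}  1/2 ||y - X w||^2  +  lam * sum_k c_k (gamma w_k + (1-gamma) w_k^2)

given G = X'X and b = X'y. Each coordinate has a closed-form non-negative
soft-thresholded update; the residual inner products are maintained
incrementally. Kernels are JIT-compiled with numba; sweeps stop when the
largest coordinate move falls below ``tol``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def nncd(G, b, c, lam, gamma, w, tol, max_sweeps):
    """One penalized non-negative LS solve in Gram form; ``w`` updated in place."""
    K = b.shape[0]
    q = G @ w  # q_k = sum_j G_kj w_j
    for _ in range(max_sweeps):
        max_delta = 0.0
        for k in range(K):
            g_kk = G[k, k]
            den = g_kk + 2.0 * lam * c[k] * (1.0 - gamma)
            if den <= 0.0:
                continue
            rest = q[k] - g_kk * w[k]
            num = b[k] - rest - lam * c[k] * gamma
            w_new = num / den if num > 0.0 else 0.0
            d = w_new - w[k]
            if d != 0.0:
                for j in range(K):
                    q[j] += G[j, k] * d
                w[k] = w_new
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            break
    return w


@njit(cache=False)
def nncd_path(G, b, c, lams, gamma, tol, max_sweeps):
    """Warm-started solves along a descending lambda path; returns (n_lam, K)."""
    n_lam = lams.shape[0]
    K = b.shape[0]
    W = np.zeros((n_lam, K))
    w = np.zeros(K)
    for j in range(n_lam):
        nncd(G, b, c, lams[j], gamma, w, tol, max_sweeps)
        W[j] = w
    return W


def solve_nncd(
    G: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    lam: float,
    gamma: float,
    w0: np.ndarray | None = None,
    tol: float = 1e-13,
    max_sweeps: int = 100_000,
) -> np.ndarray:
    """Python entry point for a single solve (copies the warm start)."""
    w = np.zeros_like(b) if w0 is None else np.array(w0, dtype=float)
    return nncd(
        np.ascontiguousarray(G, dtype=float),
        np.ascontiguousarray(b, dtype=float),
        np.ascontiguousarray(c, dtype=float),
        float(lam),
        float(gamma),
        w,
        tol,
        max_sweeps,
    )
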