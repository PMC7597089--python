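"""Compiled Euler-Maruyama inner loops for linear-coefficient models."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def euler_linear_1d(b1: float, b2: float, sigma: float, x0: float, h: float, z):
    """Scalar OU-type recursion x_{k+1} = x_k + (b1 x_k + b2) h + sigma sqrt(h) z_k."""
    n = z.shape[0]
    out = np.empty(n + 1)
    out[0] = x0
    x = x0
    s = np.sqrt(h)
    for k in range(n):
        x = x + (b1 * x + b2) * h + sigma * s * z[k]
        out[k + 1] = x
    return out


@njit(cache=True)
def euler_linear_nd(B, c, L, x0, h: float, z):
    """Vector linear recursion x_{k+1} = x_k + (B x_k + c) h + L sqrt(h) z_k."""
    n, r = z.shape
    d = x0.shape[0]
    out = np.empty((n + 1, d))
    x = x0.copy()
    out[0] = x
    s = np.sqrt(h)
    xn = np.empty(d)
    for k in range(n):
        for i in range(d):
            drift = c[i]
            for j in range(d):
                drift += B[i, j] * x[j]
            noise = 0.0
            for j in range(r):
                noise += L[i, j] * z[k, j]
            xn[i] = x[i] + drift * h + noise * s
        for i in range(d):
            x[i] = xn[i]
            out[k + 1, i] = xn[i]
    return out
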