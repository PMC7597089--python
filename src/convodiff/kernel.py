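"""Population covariance structure of moving-average observations of a diffusion.

A latent diffusion observed through a backward rectangular moving average of
width ``rho_i * h`` on axis ``i`` (``rho_i = 0`` meaning direct observation) has
one-step increments whose scaled covariance matrix converges entrywise to
``A[i, j] * fG(rho_i, rho_j)``, where ``A = a a^T`` is the diffusion matrix of
the latent process.  This module provides

* :func:`fG` — the deflation factor of the increment covariance, a continuous
  piecewise-rational function of the two window widths;
* :func:`G_matrix` — the limiting increment covariance ``A ∘ fG``;
* :func:`qv_limit_full` / :func:`qv_limit_reduced` — the probability limits of
  the full (one-step) and reduced (two-step, even-index) quadratic variations,
  as multiples of the invariant-measure integral of ``A[i, i]``;
* :func:`ratio_R` and :func:`ratio_R_inverse` — the strictly decreasing
  full/reduced QV ratio and its inverse, which identify the smoothing
  parameter from data;
* :func:`covariance_oracle` — an independent numerical evaluation of the same
  increment covariance straight from the Brownian ``min`` kernel, used to
  cross-check every closed-form branch.

All window widths are expressed in units of the sampling step ``h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_RHO_BAR",
    "SmoothingParams",
    "fG",
    "fg_matrix",
    "G_matrix",
    "qv_limit_full",
    "qv_limit_reduced",
    "ratio_R",
    "ratio_R_min",
    "ratio_R_inverse",
    "covariance_oracle",
]

#: Default upper bound of the smoothing-parameter space [0, rho_bar]^d.
DEFAULT_RHO_BAR = 100.0


@dataclass(frozen=True)
class SmoothingParams:
    """Smoothing parameter vector ``rho`` with its box bound ``rho_bar``.

    ``rho[i]`` is the moving-average window width of axis ``i`` in units of the
    sampling step; ``rho[i] = 0`` means the axis is observed directly.  The
    parameter space is the box ``[0, rho_bar]^d`` with ``rho_bar > 2`` (the
    regime in which the QV-ratio inversion has its three analytic branches).
    """

    rho: np.ndarray
    rho_bar: float = DEFAULT_RHO_BAR

    def __post_init__(self) -> None:
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if rho.ndim != 1:
            raise ValueError("rho must be a vector")
        object.__setattr__(self, "rho", rho)
        if not self.rho_bar > 2.0:
            raise ValueError(f"rho_bar must exceed 2, got {self.rho_bar}")
        if np.any(rho < 0.0) or np.any(rho > self.rho_bar):
            raise ValueError(
                f"rho must lie in [0, {self.rho_bar}], got {rho.tolist()}"
            )

    @property
    def d(self) -> int:
        return self.rho.shape[0]


def _check_window(value: float, rho_bar: float, name: str = "rho") -> float:
    value = float(value)
    if not 0.0 <= value <= rho_bar:
        raise ValueError(f"{name}={value} outside the domain [0, {rho_bar}]")
    return value


def fG(s: float, t: float, rho_bar: float = DEFAULT_RHO_BAR) -> float:
    """Increment-covariance deflation factor of two smoothed axes.

    ``fG(s, t)`` is the limit of ``Cov(dXbar_s, dXbar_t) / (A h)`` for one-step
    increments of the moving averages with window widths ``s`` and ``t`` (in
    sampling steps) of the same latent axis-pair.  Symmetric, continuous, equal
    to 1 iff both axes are observed directly.
    """
    s = _check_window(s, rho_bar, "s")
    t = _check_window(t, rho_bar, "t")
    u, v = (s, t) if s <= t else (t, s)
    # windows below one part in 10^12 of a step are numerically direct
    # observation (fG is continuous there, so the error is of the same order)
    if u < 1e-12:
        u = 0.0
    if v < 1e-12:
        v = 0.0
    if v == 0.0:
        return 1.0
    if u == 0.0:
        if v <= 1.0:
            return 1.0 - v / 2.0
        return 1.0 / (2.0 * v)
    if v <= 1.0:
        return (3 * u * u * v - 3 * u * v * v + 6 * u * v - 2 * u**3) / (6 * u * v)
    if u <= 1.0:
        if v <= u + 1.0:
            return (-((u - v) ** 3) + 6 * u * v - u**3 - 3 * v * v + 3 * v - 1.0) / (
                6 * u * v
            )
        return (3 * u * u + 3 * u - u**3) / (6 * u * v)
    if v <= u + 1.0:
        return (
            (v - u) ** 3 - 3 * u * u - 3 * v * v + 6 * u * v + 3 * u + 3 * v - 2.0
        ) / (6 * u * v)
    return (6 * u - 1.0) / (6 * u * v)


def fg_matrix(params: SmoothingParams) -> np.ndarray:
    """The d x d matrix ``F[i, j] = fG(rho_i, rho_j)``."""
    rho = params.rho
    d = rho.shape[0]
    out = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            out[i, j] = out[j, i] = fG(rho[i], rho[j], params.rho_bar)
    return out


def G_matrix(A: np.ndarray, params: SmoothingParams) -> np.ndarray:
    """Limiting one-step increment covariance ``G = A ∘ fG`` (Hadamard).

    ``A`` must be a symmetric PSD matrix (the diffusion matrix ``a a^T``
    evaluated at a state); the entrywise product with the PSD matrix
    ``fG(rho_i, rho_j)`` is again symmetric PSD by the Schur product theorem.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"A must be square, got shape {A.shape}")
    if A.shape[0] != params.d:
        raise ValueError(
            f"dimension mismatch: A is {A.shape[0]}x{A.shape[0]}, rho has d={params.d}"
        )
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("A must be symmetric")
    return A * fg_matrix(params)


def qv_limit_full(rho_i: float, rho_bar: float = DEFAULT_RHO_BAR) -> float:
    """Scale factor of the full (one-step) quadratic-variation limit.

    Equals ``fG(rho, rho)``: 1 at 0, ``1 - rho/3`` on (0, 1],
    ``1/rho - 1/(3 rho^2)`` on (1, rho_bar].
    """
    rho = _check_window(rho_i, rho_bar)
    if rho == 0.0:
        return 1.0
    if rho <= 1.0:
        return 1.0 - rho / 3.0
    return 1.0 / rho - 1.0 / (3.0 * rho * rho)


def qv_limit_reduced(rho_i: float, rho_bar: float = DEFAULT_RHO_BAR) -> float:
    """Scale factor of the reduced (two-step, even-index) QV limit.

    1 at 0, ``1 - rho/6`` on (0, 2], ``(6 rho - 4) / (3 rho^2)`` on
    (2, rho_bar]; continuous at 2 where both branches give 2/3.
    """
    rho = _check_window(rho_i, rho_bar)
    if rho == 0.0:
        return 1.0
    if rho <= 2.0:
        return 1.0 - rho / 6.0
    return (6.0 * rho - 4.0) / (3.0 * rho * rho)


def ratio_R(rho_i: float, rho_bar: float = DEFAULT_RHO_BAR) -> float:
    """Population full/reduced QV ratio ``R(rho)``.

    Strictly decreasing from 1 at ``rho = 0`` down to
    ``(3 rho_bar - 1) / (6 rho_bar - 4)`` at ``rho = rho_bar``:
    ``(6 - 2 rho)/(6 - rho)`` on (0, 1], ``(6 rho - 2)/(6 rho^2 - rho^3)`` on
    (1, 2], ``(3 rho - 1)/(6 rho - 4)`` on (2, rho_bar].
    """
    rho = _check_window(rho_i, rho_bar)
    if rho == 0.0:
        return 1.0
    if rho <= 1.0:
        return (6.0 - 2.0 * rho) / (6.0 - rho)
    if rho <= 2.0:
        return (6.0 * rho - 2.0) / (6.0 * rho * rho - rho**3)
    return (3.0 * rho - 1.0) / (6.0 * rho - 4.0)


def ratio_R_min(rho_bar: float = DEFAULT_RHO_BAR) -> float:
    """Infimum of the QV ratio over [0, rho_bar] (attained at rho_bar)."""
    if not rho_bar > 2.0:
        raise ValueError("rho_bar must exceed 2")
    return (3.0 * rho_bar - 1.0) / (6.0 * rho_bar - 4.0)


def ratio_R_inverse(x: float, rho_bar: float = DEFAULT_RHO_BAR) -> float:
    """Inverse of :func:`ratio_R` on its open range.

    Branches: for ``x in [4/5, 1)`` the linear solution ``6(1-x)/(2-x)``; for
    ``x in [5/8, 4/5)`` the unique root in (1, 2] of
    ``x (6y^2 - y^3) = 6y - 2`` (bracketed root-finding, the cubic is monotone
    there); for ``x in (ratio_R_min, 5/8)`` the linear solution
    ``(4x - 1)/(6x - 3)``.  Raises for ``x`` outside the open interval —
    callers clamp out-of-range ratios to 0 or ``rho_bar``.
    """
    x = float(x)
    lo = ratio_R_min(rho_bar)
    if not lo < x < 1.0:
        raise ValueError(f"x={x} outside the invertible range ({lo}, 1)")
    if x >= 0.8:
        return 6.0 * (1.0 - x) / (2.0 - x)
    if x >= 0.625:
        if x == 0.625:
            return 2.0

        def _f(y: float) -> float:
            return x * (6.0 * y * y - y**3) - (6.0 * y - 2.0)

        return float(brentq(_f, 1.0, 2.0, xtol=1e-12, rtol=8.9e-16))
    return (4.0 * x - 1.0) / (6.0 * x - 3.0)


def _window_points(width: float, end: float, n_grid: int, sign: float):
    """Midpoint discretisation of a rectangular averaging window ending at ``end``.

    Returns sample times and weights of the signed average
    ``sign * (1/width) * integral over [end - width, end]``; a zero width is the
    Dirac case (direct observation) represented by a single unit mass at ``end``.
    """
    if width == 0.0:
        return np.array([end]), np.array([sign])
    offsets = (np.arange(n_grid) + 0.5) * (width / n_grid)
    return end - offsets, np.full(n_grid, sign / n_grid)


def _min_kernel_cross(tau_a, w_a, tau_b, w_b) -> float:
    """``sum_{i,j} w_a[i] w_b[j] min(tau_a[i], tau_b[j])`` in O(K log K).

    Uses ``min(a, b) = integral_0^inf 1(u < a) 1(u < b) du`` so the double sum
    is the integral of the product of two step functions
    ``S(u) = sum of weights with sample time > u``.
    """
    order_a = np.argsort(tau_a)
    tau_a, w_a = tau_a[order_a], w_a[order_a]
    order_b = np.argsort(tau_b)
    tau_b, w_b = tau_b[order_b], w_b[order_b]
    grid = np.unique(np.concatenate([tau_a, tau_b, [0.0]]))
    # suffix sums: S(u) for u just right of each grid point
    suff_a = np.concatenate([np.cumsum(w_a[::-1])[::-1], [0.0]])
    suff_b = np.concatenate([np.cumsum(w_b[::-1])[::-1], [0.0]])
    ia = np.searchsorted(tau_a, grid[:-1], side="right")
    ib = np.searchsorted(tau_b, grid[:-1], side="right")
    return float(np.sum(suff_a[ia] * suff_b[ib] * np.diff(grid)))


def covariance_oracle(
    s: float,
    t: float,
    n_grid: int = 2000,
    *,
    two_step: bool = False,
) -> float:
    """Numerical increment covariance of two moving averages of Brownian motion.

    Computes, with unit sampling step ``h = 1`` and windows anchored at
    ``Delta = max(s, t)`` so both lie in positive time,
    ``Cov(Xbar_s(Delta + k) - Xbar_s(Delta), Xbar_t(Delta + k) - Xbar_t(Delta)) / k``
    for a standard Brownian latent path, with ``k = 1`` (or ``k = 2`` when
    ``two_step``), using the exact Brownian kernel ``min(u, u')`` and a
    midpoint discretisation of each averaging window with ``n_grid`` points.
    Converges to :func:`fG` (diagonal two-step: :func:`qv_limit_reduced`) as
    ``n_grid`` grows; entirely independent of the closed-form branches.
    """
    if s < 0.0 or t < 0.0:
        raise ValueError("window widths must be non-negative")
    if n_grid < 10:
        raise ValueError("n_grid too small")
    step = 2.0 if two_step else 1.0
    if s == 0.0 and t == 0.0:
        # direct observation on both axes: Var(W(Delta+k) - W(Delta)) = k
        return 1.0
    delta = max(s, t)
    pa1, wa1 = _window_points(s, delta + step, n_grid, +1.0)
    pa0, wa0 = _window_points(s, delta, n_grid, -1.0)
    pb1, wb1 = _window_points(t, delta + step, n_grid, +1.0)
    pb0, wb0 = _window_points(t, delta, n_grid, -1.0)
    tau_a = np.concatenate([pa1, pa0])
    w_a = np.concatenate([wa1, wa0])
    tau_b = np.concatenate([pb1, pb0])
    w_b = np.concatenate([wb1, wb0])
    return _min_kernel_cross(tau_a, w_a, tau_b, w_b) / step
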