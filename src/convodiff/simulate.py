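"""Euler-Maruyama simulation and convolution-by-summation observation.

The experimental pipeline: a latent diffusion path is iterated on a fine grid
``h_sim = h * 10^{-m}`` (Euler-Maruyama), including a burn-in segment before
``t = 0`` long enough to cover every moving-average window, and the smoothed
observation on axis ``l`` is the running mean of the last
``K_l = round(10^m * rho_l)`` fine-grid states ending at each sampling time
(direct observation when the window is shorter than one fine step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .kernel import SmoothingParams, DEFAULT_RHO_BAR
from .models import DiffusionModel
from .series import ConvObsSeries

__all__ = [
    "SimulationConfig",
    "euler_maruyama",
    "convolve_observations",
    "simulate_convobs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design constants of one simulated experiment.

    ``n`` observations at step ``h``; the latent path is refined by
    ``10^m`` (``h_sim = h * 10^-m``).  ``burn_in_steps`` counts fine steps
    simulated before ``t = 0``; when ``None`` it is resolved to
    ``(ceil(max rho) + 1) * 10^m``, which always covers the convolution
    window.  ``x0`` is the state at the start of the burn-in.
    """

    n: int
    h: float
    m: int = 2
    burn_in_steps: Optional[int] = None
    x0: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not self.h > 0:
            raise ValueError("h must be positive")
        if self.m < 1:
            raise ValueError("refinement exponent m must be >= 1")
        if self.burn_in_steps is not None and self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be non-negative")

    @property
    def refine(self) -> int:
        return 10**self.m

    @property
    def h_sim(self) -> float:
        return self.h / self.refine

    def resolve_burn_in(self, rho: SmoothingParams | np.ndarray) -> "SimulationConfig":
        """Fill in the default burn-in for the given smoothing parameter."""
        if self.burn_in_steps is not None:
            return self
        rho_arr = rho.rho if isinstance(rho, SmoothingParams) else np.atleast_1d(rho)
        burn = (math.ceil(float(np.max(rho_arr))) + 1) * self.refine
        return replace(self, burn_in_steps=burn)


def _x0_vector(cfg: SimulationConfig, d: int) -> np.ndarray:
    x0 = np.atleast_1d(np.asarray(cfg.x0, dtype=float))
    if x0.shape == (1,) and d > 1:
        x0 = np.full(d, x0[0])
    if x0.shape != (d,):
        raise ValueError(f"x0 must have {d} entries")
    return x0


def euler_maruyama(
    model: DiffusionModel,
    alpha: np.ndarray,
    beta: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Simulate the fine-grid latent path, burn-in included.

    Returns an array of ``burn_in_steps + n * 10^m + 1`` states (shape
    ``(steps + 1, d)``); the state at fine index ``burn_in_steps`` is the
    process at ``t = 0``.  Deterministic given ``cfg.seed``.  Models declaring
    ``linear_coeffs`` use a compiled loop; any other model is iterated through
    its drift/diffusion callables.
    """
    alpha = model.check_alpha(alpha)
    beta = model.check_beta(beta)
    burn = cfg.burn_in_steps if cfg.burn_in_steps is not None else cfg.refine
    steps = burn + cfg.n * cfg.refine
    x0 = _x0_vector(cfg, model.d)
    rng = np.random.default_rng(cfg.seed)
    if model.linear_coeffs is not None:
        B, c, L = model.linear_coeffs(alpha, beta)
        if model.d == 1 and model.r == 1:
            z = rng.standard_normal(steps)
            from ._euler import euler_linear_1d

            path = euler_linear_1d(
                float(B[0, 0]), float(c[0]), float(L[0, 0]), float(x0[0]),
                cfg.h_sim, z,
            )[:, None]
        else:
            z = rng.standard_normal((steps, model.r))
            from ._euler import euler_linear_nd

            path = euler_linear_nd(
                np.asarray(B, dtype=float),
                np.asarray(c, dtype=float),
                np.asarray(L, dtype=float),
                x0, cfg.h_sim, z,
            )
    else:
        path = np.empty((steps + 1, model.d))
        path[0] = x0
        x = x0.copy()
        sqrt_h = math.sqrt(cfg.h_sim)
        z = rng.standard_normal((steps, model.r))
        for k in range(steps):
            x = (
                x
                + np.atleast_1d(model.drift(x, beta)) * cfg.h_sim
                + np.atleast_2d(model.diffusion(x, alpha)) @ z[k] * sqrt_h
            )
            path[k + 1] = x
    finite = np.isfinite(path).all(axis=1)
    if not finite.all():
        bad = int(np.argmin(finite))
        raise FloatingPointError(
            f"Euler-Maruyama path exploded (non-finite state) at fine step {bad}"
        )
    return path


def convolve_observations(
    fine_path: np.ndarray,
    cfg: SimulationConfig,
    rho: SmoothingParams | np.ndarray,
) -> ConvObsSeries:
    """Average the fine path over each axis's moving window at sampling times.

    Axis ``l`` with ``K_l = round(10^m * rho_l) >= 1`` yields
    ``Xbar_{ih} = (1/K_l) * sum_{k=0}^{K_l-1} X_{ih - k h_sim}``; a window
    shorter than one fine step yields the direct observation ``X_{ih}``.
    The position of ``t = 0`` inside the fine path is inferred from its length.
    """
    fine = np.asarray(fine_path, dtype=float)
    if fine.ndim == 1:
        fine = fine[:, None]
    rho_arr = rho.rho if isinstance(rho, SmoothingParams) else np.atleast_1d(
        np.asarray(rho, dtype=float)
    )
    d = fine.shape[1]
    if rho_arr.shape != (d,):
        raise ValueError(f"rho must have {d} entries to match the path")
    refine = cfg.refine
    burn = fine.shape[0] - 1 - cfg.n * refine
    if burn < 0:
        raise ValueError("fine path shorter than n * 10^m observation steps")
    if cfg.burn_in_steps is not None and burn != cfg.burn_in_steps:
        raise ValueError(
            f"fine path implies burn-in {burn}, config says {cfg.burn_in_steps}"
        )
    obs_idx = burn + refine * np.arange(cfg.n + 1)
    out = np.empty((cfg.n + 1, d))
    for l in range(d):
        K = int(round(refine * rho_arr[l]))
        if K < 1:
            out[:, l] = fine[obs_idx, l]
            continue
        if K - 1 > burn:
            raise ValueError(
                f"axis {l}: window of {K} fine steps exceeds burn-in of {burn}"
            )
        cs = np.concatenate([[0.0], np.cumsum(fine[:, l])])
        out[:, l] = (cs[obs_idx + 1] - cs[obs_idx + 1 - K]) / K
    return ConvObsSeries(out, cfg.h)


def simulate_convobs(
    model: DiffusionModel,
    alpha: np.ndarray,
    beta: np.ndarray,
    rho: SmoothingParams | np.ndarray,
    cfg: SimulationConfig,
) -> ConvObsSeries:
    """Simulate the latent path and return its convolutional observation."""
    rho_params = (
        rho
        if isinstance(rho, SmoothingParams)
        else SmoothingParams(np.atleast_1d(np.asarray(rho, dtype=float)),
                             max(DEFAULT_RHO_BAR, float(np.max(np.atleast_1d(rho))) + 1))
    )
    if rho_params.d != model.d:
        raise ValueError("rho dimension must match the model")
    cfg = cfg.resolve_burn_in(rho_params)
    fine = euler_maruyama(model, alpha, beta, cfg)
    return convolve_observations(fine, cfg, rho_params)
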