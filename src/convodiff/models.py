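"""Diffusion model specifications and the Ornstein-Uhlenbeck presets.

A :class:`DiffusionModel` bundles the drift ``b(x, beta)`` and diffusion
``a(x, alpha)`` coefficient functions of the latent SDE

    dX_t = b(X_t, beta) dt + a(X_t, alpha) dw_t

together with the compact box parameter spaces over which the least-square
quasi-likelihoods are maximised.  Optional structural declarations (linear
coefficients, state-independent diffusion, drift linear in beta) unlock fast
simulation and sufficient-statistic reductions of the contrasts; they never
change the definitions, only the evaluation route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["DiffusionModel", "ou_preset_1d", "ou_preset_2d"]


@dataclass
class DiffusionModel:
    """Parametric SDE specification with compact parameter boxes.

    Parameters
    ----------
    d, r : state and driving-noise dimensions.
    drift : callable ``(x, beta) -> (d,)`` drift vector at state ``x``.
    diffusion : callable ``(x, alpha) -> (d, r)`` diffusion matrix at ``x``.
    theta1_box, theta2_box : ``(m1, 2)`` / ``(m2, 2)`` arrays of finite
        ``(lower, upper)`` bounds for ``alpha`` and ``beta``.
    linear_coeffs : optional ``(alpha, beta) -> (B, c, L)`` with
        ``b(x) = B x + c`` and ``a(x) = L`` constant; enables the compiled
        Euler-Maruyama path.
    diffusion_constant : declare ``a(x, alpha)`` independent of ``x``.
    scalar_diffusion : declare ``d = r = m1 = 1`` with ``a(x, alpha) = alpha``;
        enables the closed-form diffusion-parameter fast path.
    drift_design : optional ``(X: (n, d)) -> (n, d, m2)`` design tensor ``Z``
        with ``b(x_k, beta) = Z_k @ beta``; enables the quadratic
        sufficient-statistic form of the drift contrast.
    """

    d: int
    r: int
    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    diffusion: Callable[[np.ndarray, np.ndarray], np.ndarray]
    theta1_box: np.ndarray
    theta2_box: np.ndarray
    name: str = "custom"
    linear_coeffs: Optional[Callable] = None
    diffusion_constant: bool = False
    scalar_diffusion: bool = False
    drift_design: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        for attr in ("theta1_box", "theta2_box"):
            box = np.asarray(getattr(self, attr), dtype=float)
            if box.ndim != 2 or box.shape[1] != 2:
                raise ValueError(f"{attr} must have shape (m, 2)")
            if not np.all(np.isfinite(box)):
                raise ValueError(f"{attr} must be finite (compact parameter space)")
            if not np.all(box[:, 0] < box[:, 1]):
                raise ValueError(f"{attr} must have lower < upper bounds")
            setattr(self, attr, box)
        if self.d < 1 or self.r < 1:
            raise ValueError("dimensions must be positive")

    @property
    def m1(self) -> int:
        return self.theta1_box.shape[0]

    @property
    def m2(self) -> int:
        return self.theta2_box.shape[0]

    def check_alpha(self, alpha: np.ndarray) -> np.ndarray:
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        if alpha.shape != (self.m1,):
            raise ValueError(f"alpha must have {self.m1} entries")
        box = self.theta1_box
        if np.any(alpha < box[:, 0] - 1e-12) or np.any(alpha > box[:, 1] + 1e-12):
            raise ValueError(f"alpha={alpha.tolist()} outside Theta1")
        return alpha

    def check_beta(self, beta: np.ndarray) -> np.ndarray:
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        if beta.shape != (self.m2,):
            raise ValueError(f"beta must have {self.m2} entries")
        box = self.theta2_box
        if np.any(beta < box[:, 0] - 1e-12) or np.any(beta > box[:, 1] + 1e-12):
            raise ValueError(f"beta={beta.tolist()} outside Theta2")
        return beta


def ou_preset_1d() -> DiffusionModel:
    """1-D Ornstein-Uhlenbeck model ``dX = (b1 X + b2) dt + alpha dw``.

    Boxes: ``alpha in [0.01, 10]``, ``beta in [-10, -0.01] x [-10, 10]`` (the
    mean-reversion rate ``b1`` is kept negative so the process is ergodic).
    """

    def drift(x, beta):
        x = np.atleast_1d(x)
        return np.array([beta[0] * x[0] + beta[1]])

    def diffusion(x, alpha):
        return np.array([[alpha[0]]])

    def linear_coeffs(alpha, beta):
        return (
            np.array([[beta[0]]]),
            np.array([beta[1]]),
            np.array([[alpha[0]]]),
        )

    def drift_design(X):
        X = np.asarray(X, dtype=float).reshape(-1, 1)
        n = X.shape[0]
        Z = np.empty((n, 1, 2))
        Z[:, 0, 0] = X[:, 0]
        Z[:, 0, 1] = 1.0
        return Z

    return DiffusionModel(
        d=1,
        r=1,
        drift=drift,
        diffusion=diffusion,
        theta1_box=np.array([[0.01, 10.0]]),
        theta2_box=np.array([[-10.0, -0.01], [-10.0, 10.0]]),
        name="ou1d",
        linear_coeffs=linear_coeffs,
        diffusion_constant=True,
        scalar_diffusion=True,
        drift_design=drift_design,
    )


def ou_preset_2d() -> DiffusionModel:
    """2-D Ornstein-Uhlenbeck model with full linear drift and symmetric diffusion.

    Drift ``b(x, beta) = [[b1, b2], [b4, b5]] x + (b3, b6)``; diffusion
    ``a(alpha) = [[a1, a2], [a2, a3]]`` constant in the state.  Boxes:
    ``alpha in [1+1e-8, 10] x [-1+1e-8, 1-1e-8] x [1+1e-8, 10]``,
    ``beta in [-10, 10]^6``.
    """
    eps = 1e-8

    def _bmat(beta):
        return np.array([[beta[0], beta[1]], [beta[3], beta[4]]])

    def _cvec(beta):
        return np.array([beta[2], beta[5]])

    def _amat(alpha):
        return np.array([[alpha[0], alpha[1]], [alpha[1], alpha[2]]])

    def drift(x, beta):
        return _bmat(beta) @ np.atleast_1d(x) + _cvec(beta)

    def diffusion(x, alpha):
        return _amat(alpha)

    def linear_coeffs(alpha, beta):
        return _bmat(beta), _cvec(beta), _amat(alpha)

    def drift_design(X):
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        n = X.shape[0]
        Z = np.zeros((n, 2, 6))
        Z[:, 0, 0] = X[:, 0]
        Z[:, 0, 1] = X[:, 1]
        Z[:, 0, 2] = 1.0
        Z[:, 1, 3] = X[:, 0]
        Z[:, 1, 4] = X[:, 1]
        Z[:, 1, 5] = 1.0
        return Z

    return DiffusionModel(
        d=2,
        r=2,
        drift=drift,
        diffusion=diffusion,
        theta1_box=np.array(
            [[1.0 + eps, 10.0], [-1.0 + eps, 1.0 - eps], [1.0 + eps, 10.0]]
        ),
        theta2_box=np.tile([-10.0, 10.0], (6, 1)),
        name="ou2d",
        linear_coeffs=linear_coeffs,
        diffusion_constant=True,
        drift_design=drift_design,
    )
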