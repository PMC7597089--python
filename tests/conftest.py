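"""Shared fixtures: models, small simulated series, design constants."""

from __future__ import annotations

import numpy as np
import pytest

from convodiff import (
    ConvObsSeries,
    SimulationConfig,
    ou_preset_1d,
    ou_preset_2d,
    simulate_convobs,
)

#: Sampling step of the reference OU designs.
DESIGN_H = 10.0 ** (-10.0 / 3.0)


@pytest.fixture(scope="session")
def ou1d():
    return ou_preset_1d()


@pytest.fixture(scope="session")
def ou2d():
    return ou_preset_2d()


@pytest.fixture(scope="session")
def sim1d():
    """Factory for small/medium 1-D OU simulations (default desk-size n)."""

    def make(rho: float, n: int = 20_000, seed: int = 0, m: int = 2,
             alpha: float = 3.0, beta=(-2.0, 1.0)) -> ConvObsSeries:
        model = ou_preset_1d()
        cfg = SimulationConfig(n=n, h=DESIGN_H, m=m, seed=seed)
        return simulate_convobs(model, [alpha], list(beta), [rho], cfg)

    return make


@pytest.fixture(scope="session")
def sim2d():
    def make(rho=(2.0, 4.0), n: int = 20_000, seed: int = 0, m: int = 2):
        model = ou_preset_2d()
        cfg = SimulationConfig(n=n, h=DESIGN_H, m=m, seed=seed)
        return simulate_convobs(
            model, [2.0, 0.0, 3.0], [-2.0, -0.4, 0.0, 0.1, -3.0, 5.0], list(rho), cfg
        )

    return make


@pytest.fixture()
def bm_series():
    """Directly observed standard Brownian motion (unit diffusion)."""

    def make(n: int = 20_000, h: float = 1e-3, seed: int = 1, d: int = 1):
        rng = np.random.default_rng(seed)
        incr = rng.standard_normal((n, d)) * np.sqrt(h)
        values = np.vstack([np.zeros((1, d)), np.cumsum(incr, axis=0)])
        return ConvObsSeries(values, h)

    return make
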