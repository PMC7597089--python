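"""Closed-form covariance factors vs the independent Brownian-kernel oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convodiff.kernel import (
    DEFAULT_RHO_BAR,
    G_matrix,
    SmoothingParams,
    covariance_oracle,
    fG,
    qv_limit_full,
    qv_limit_reduced,
    ratio_R,
    ratio_R_inverse,
    ratio_R_min,
)

windows = st.floats(0.0, 3.0, allow_nan=False)


@pytest.mark.parametrize(
    "s, t, expected",
    [
        (0.0, 0.0, 1.0),  # direct observation on both axes
        (1.0, 1.0, 2.0 / 3.0),  # integrated observation
        (2.0, 2.0, 5.0 / 12.0),  # diagonal closed form 1/rho - 1/(3 rho^2)
        (0.0, 0.5, 0.75),  # one direct axis: 1 - v/2
        (0.5, 0.0, 0.75),
    ],
)
def test_fg_reference_values(s, t, expected):
    assert fG(s, t) == pytest.approx(expected, abs=1e-12)


def test_fg_domain_error():
    with pytest.raises(ValueError):
        fG(-0.1, 1.0)
    with pytest.raises(ValueError):
        fG(1.0, 4.5, rho_bar=4.0)
    with pytest.raises(ValueError):
        fG(101.0, 1.0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(windows, windows)
def test_fg_symmetry(s, t):
    assert fG(s, t) == pytest.approx(fG(t, s), abs=1e-12)


@pytest.mark.parametrize("u", [0.2, 0.5, 0.8, 1.0, 1.4, 2.0, 2.7])
def test_fg_continuity_at_seams(u):
    """fG agrees across each branch boundary (v crossing 1, u, and u+1)."""
    eps = 1e-9
    for v_seam in (1.0, u, u + 1.0):
        if v_seam < u:
            continue
        left = fG(u, max(v_seam - eps, 0.0))
        right = fG(u, v_seam + eps)
        assert left == pytest.approx(right, abs=1e-7)
    # the direct-observation seam: v -> 0+
    assert fG(u, eps) == pytest.approx(fG(u, 0.0), abs=1e-7)


def test_fg_matches_oracle_on_grid():
    """Every closed-form branch agrees with the Brownian min-kernel quadrature."""
    pts = np.linspace(0.0, 3.0, 12)
    err = max(
        abs(fG(s, t) - covariance_oracle(s, t, n_grid=2000)) for s in pts for t in pts
    )
    assert err < 1e-3


def test_oracle_dirac_and_convergence():
    assert covariance_oracle(0.0, 0.0) == 1.0
    assert covariance_oracle(1.0, 1.0, n_grid=2000) == pytest.approx(2 / 3, abs=1e-4)
    assert covariance_oracle(0.3, 1.7, n_grid=2000) == pytest.approx(
        fG(0.3, 1.7), abs=1e-4
    )
    # refinement improves agreement
    coarse = abs(covariance_oracle(0.7, 1.2, n_grid=50) - fG(0.7, 1.2))
    fine = abs(covariance_oracle(0.7, 1.2, n_grid=3000) - fG(0.7, 1.2))
    assert fine <= coarse


@pytest.mark.parametrize(
    "rho, expected",
    [(0.0, 1.0), (1.0, 2.0 / 3.0), (10.0, 0.1 - 1.0 / 300.0)],
)
def test_qv_limit_full_values(rho, expected):
    assert qv_limit_full(rho) == pytest.approx(expected, abs=1e-12)
    assert qv_limit_full(rho) == pytest.approx(fG(rho, rho), abs=1e-12)


@pytest.mark.parametrize(
    "rho, expected",
    [(0.0, 1.0), (2.0, 2.0 / 3.0), (3.0, 14.0 / 27.0)],
)
def test_qv_limit_reduced_values(rho, expected):
    assert qv_limit_reduced(rho) == pytest.approx(expected, abs=1e-12)


def test_qv_limit_reduced_matches_two_step_oracle():
    for rho in (0.5, 1.3, 2.0, 3.0):
        assert covariance_oracle(rho, rho, 2000, two_step=True) == pytest.approx(
            qv_limit_reduced(rho), abs=1e-4
        )


def test_limits_continuous_at_seams():
    eps = 1e-10
    assert qv_limit_full(1.0) == pytest.approx(qv_limit_full(1.0 + eps), abs=1e-8)
    assert qv_limit_reduced(2.0) == pytest.approx(qv_limit_reduced(2.0 + eps), abs=1e-8)
    assert ratio_R(1.0) == pytest.approx(4.0 / 5.0, abs=1e-14)
    assert ratio_R(2.0) == pytest.approx(5.0 / 8.0, abs=1e-14)
    assert ratio_R(1.0 + eps) == pytest.approx(4.0 / 5.0, abs=1e-8)
    assert ratio_R(2.0 + eps) == pytest.approx(5.0 / 8.0, abs=1e-8)


def test_ratio_values():
    assert ratio_R(3.0) == pytest.approx(4.0 / 7.0, abs=1e-14)
    assert ratio_R(0.0) == 1.0


def test_ratio_strictly_decreasing():
    grid = np.linspace(0.0, DEFAULT_RHO_BAR, 400)
    vals = [ratio_R(r) for r in grid]
    assert np.all(np.diff(vals) < 0)


@pytest.mark.parametrize("x, expected", [(0.8, 1.0), (0.625, 2.0)])
def test_ratio_inverse_branch_boundaries(x, expected):
    assert ratio_R_inverse(x) == pytest.approx(expected, abs=1e-10)


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.floats(1e-3, DEFAULT_RHO_BAR - 1e-3))
def test_ratio_inverse_roundtrip(rho):
    x = ratio_R(rho)
    assert ratio_R_inverse(x) == pytest.approx(rho, abs=1e-8)
    assert ratio_R(ratio_R_inverse(x)) == pytest.approx(x, abs=1e-10)


def test_ratio_inverse_domain_errors():
    with pytest.raises(ValueError):
        ratio_R_inverse(1.0)
    with pytest.raises(ValueError):
        ratio_R_inverse(ratio_R_min(DEFAULT_RHO_BAR))


def test_g_matrix_identity_and_values():
    A = np.array([[2.0, 0.3], [0.3, 1.5]])
    G = G_matrix(A, SmoothingParams(np.zeros(2)))
    np.testing.assert_allclose(G, A)
    G1 = G_matrix(np.array([[9.0]]), SmoothingParams(np.array([1.0])))
    assert G1[0, 0] == pytest.approx(6.0)
    G2 = G_matrix(np.diag([4.0, 9.0]), SmoothingParams(np.array([2.0, 4.0])))
    assert G2[0, 0] == pytest.approx(4.0 * 5.0 / 12.0)
    assert G2[1, 1] == pytest.approx(9.0 * (0.25 - 1.0 / 48.0))
    assert G2[0, 1] == 0.0


def test_g_matrix_psd_property():
    rng = np.random.default_rng(42)
    for _ in range(25):
        d = rng.integers(1, 5)
        M = rng.standard_normal((d, d))
        A = M @ M.T
        rho = rng.uniform(0.0, 8.0, d)
        G = G_matrix(A, SmoothingParams(rho))
        assert np.min(np.linalg.eigvalsh(G)) >= -1e-10


def test_g_matrix_errors():
    with pytest.raises(ValueError):
        G_matrix(np.ones((2, 3)), SmoothingParams(np.zeros(2)))
    with pytest.raises(ValueError):
        G_matrix(np.array([[1.0, 2.0], [0.0, 1.0]]), SmoothingParams(np.zeros(2)))


def test_smoothing_params_validation():
    with pytest.raises(ValueError):
        SmoothingParams(np.array([-0.1]))
    with pytest.raises(ValueError):
        SmoothingParams(np.array([3.0]), rho_bar=2.0)
    with pytest.raises(ValueError):
        SmoothingParams(np.array([4.5]), rho_bar=4.0)
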