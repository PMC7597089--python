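"""Least-square quasi-likelihood contrasts and parameter estimation."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.base import clone

from convodiff import (
    ConvObsSeries,
    ConvolutionLeastSquares,
    DiffusionModel,
    LGAEstimator,
    OptimiserConfig,
    estimate_alpha,
    estimate_beta,
    fit,
    h1_objective,
    h2_objective,
    lga_fit,
)
from convodiff.fitting import drift_lag


def _no_structure(model: DiffusionModel) -> DiffusionModel:
    """Same model with every fast-path declaration stripped."""
    return DiffusionModel(
        d=model.d, r=model.r, drift=model.drift, diffusion=model.diffusion,
        theta1_box=model.theta1_box, theta2_box=model.theta2_box,
    )


def test_objectives_are_nonpositive(sim1d, ou1d):
    series = sim1d(0.5, n=2_000, seed=3)
    for alpha in ([0.5], [3.0], [9.0]):
        assert h1_objective(series, alpha, [0.5], ou1d) <= 0.0
    for beta in ([-2.0, 1.0], [-0.5, -3.0]):
        assert h2_objective(series, beta, [0.5], ou1d) <= 0.0


def test_h1_at_rho_zero_is_standard_contrast(sim1d, ou1d):
    """With rho = 0 the contrast reduces to matching (dX)^2/h to alpha^2."""
    series = sim1d(0.0, n=500, seed=4)
    diffs = np.diff(series.values[:, 0])
    for a in (1.0, 3.0):
        manual = -np.sum((diffs**2 / series.h - a**2) ** 2)
        assert h1_objective(series, [a], [0.0], ou1d) == pytest.approx(manual, rel=1e-9)


def test_suffstat_and_generic_routes_agree(sim1d, ou1d):
    series = sim1d(0.7, n=400, seed=5)
    plain = _no_structure(ou1d)
    for a in (2.0, 3.5):
        assert h1_objective(series, [a], [0.7], ou1d) == pytest.approx(
            h1_objective(series, [a], [0.7], plain), rel=1e-9
        )
    for b in ([-2.0, 1.0], [-4.0, 0.3]):
        assert h2_objective(series, b, [0.7], ou1d) == pytest.approx(
            h2_objective(series, b, [0.7], plain), rel=1e-9
        )


def test_alpha_outside_box_errors(sim1d, ou1d):
    series = sim1d(0.0, n=100, seed=6)
    with pytest.raises(ValueError):
        h1_objective(series, [50.0], [0.0], ou1d)
    with pytest.raises(ValueError):
        h2_objective(series, [5.0, 0.0], [0.0], ou1d)  # beta1 must be negative


def test_zero_drift_objective_is_beta_free(sim1d):
    model = DiffusionModel(
        d=1, r=1,
        drift=lambda x, b: np.zeros(1),
        diffusion=lambda x, a: np.array([[a[0]]]),
        theta1_box=np.array([[0.01, 10.0]]),
        theta2_box=np.array([[-1.0, 1.0]]),
    )
    series = sim1d(0.0, n=300, seed=7)
    v1 = h2_objective(series, [0.3], [0.0], model)
    v2 = h2_objective(series, [-0.8], [0.0], model)
    diffs = np.diff(series.values[:, 0])[drift_lag(np.array([0.0])) :]
    assert v1 == pytest.approx(v2)
    assert v1 == pytest.approx(-np.sum(diffs**2) / series.h, rel=1e-9)


def test_closed_form_alpha_matches_optimiser(sim1d, ou1d):
    series = sim1d(1.0, n=4_000, seed=8)
    a_cf, v_cf, info_cf = estimate_alpha(
        series, [1.0], ou1d, OptimiserConfig(closed_form=True)
    )
    a_opt, v_opt, _ = estimate_alpha(
        series, [1.0], ou1d, OptimiserConfig(closed_form=False)
    )
    assert info_cf.get("closed_form")
    assert a_cf[0] == pytest.approx(a_opt[0], abs=1e-8)
    assert v_cf == pytest.approx(v_opt, rel=1e-10)


def test_closed_form_alpha_identity_at_rho_zero(sim1d, ou1d):
    """At rho = 0 the exact maximiser is sqrt of the mean scaled square increment."""
    series = sim1d(0.0, n=2_000, seed=9)
    a_hat, _, _ = estimate_alpha(series, [0.0], ou1d)
    diffs = np.diff(series.values[:, 0])
    assert a_hat[0] ** 2 == pytest.approx(
        np.sum(diffs**2) / (series.n * series.h), rel=1e-12
    )


def test_noiseless_drift_regression_recovers_beta(ou1d):
    """A deterministic Euler path at lag 0 identifies beta exactly."""
    h, n = 0.01, 300
    beta_true = np.array([-2.0, 1.0])
    x = np.empty(n + 1)
    x[0] = 3.0
    for k in range(n):
        x[k + 1] = x[k] + (beta_true[0] * x[k] + beta_true[1]) * h
    series = ConvObsSeries(x, h)
    b_hat, value, _ = estimate_beta(series, [0.0], ou1d, lag=0)
    np.testing.assert_allclose(b_hat, beta_true, atol=1e-7)
    assert value == pytest.approx(0.0, abs=1e-10)


def test_lga_alpha_equals_known_rho_zero_fit(sim1d, ou1d):
    series = sim1d(0.0, n=3_000, seed=10)
    corrected = fit(series, ou1d, rho=[0.0])
    naive = lga_fit(series, ou1d)
    assert naive.alpha_hat[0] == corrected.alpha_hat[0]
    assert naive.method == "lga"
    assert corrected.method == "convobs"


def test_series_shorter_than_lag_errors(ou1d):
    series = ConvObsSeries(np.arange(6, dtype=float), h=0.1)
    with pytest.raises(ValueError, match="lag"):
        h2_objective(series, [-2.0, 1.0], [8.0], ou1d)


def test_plugin_fit_records_rho_and_boundary_flag(sim1d, ou1d):
    series = sim1d(1.0, n=10_000, seed=11)
    result = fit(series, ou1d, rho=None, rho_bar=100.0)
    assert result.optimiser_info["rho_mode"] == "estimated"
    assert not result.optimiser_info["rho_at_boundary"]
    assert result.rho_used[0] == pytest.approx(1.0, abs=0.3)
    assert result.h1_value <= 0.0 and result.h2_value <= 0.0
    payload = result.to_dict()
    assert set(payload) >= {"method", "rho_used", "alpha_hat", "beta_hat", "objectives"}


def test_known_rho_at_least_as_accurate_as_plugin(sim1d, ou1d):
    """Plugging in rho_hat cannot beat knowing rho, up to Monte-Carlo noise."""
    err_known, err_plug = [], []
    for r in range(6):
        series = sim1d(1.0, n=8_000, seed=200 + r)
        known = fit(series, ou1d, rho=[1.0])
        plug = fit(series, ou1d, rho=None)
        err_known.append((known.alpha_hat[0] - 3.0) ** 2)
        err_plug.append((plug.alpha_hat[0] - 3.0) ** 2)
    rmse_known = np.sqrt(np.mean(err_known))
    rmse_plug = np.sqrt(np.mean(err_plug))
    se = np.std(np.sqrt(err_plug), ddof=1) / np.sqrt(len(err_plug))
    assert rmse_known <= rmse_plug + 3 * se


def test_2d_fit_recovers_parameters(sim2d, ou2d):
    series = sim2d(rho=(2.0, 4.0), n=30_000, seed=12)
    result = fit(series, ou2d, rho_bar=10.0)
    np.testing.assert_allclose(result.alpha_hat, [2.0, 0.0, 3.0], atol=0.15)
    naive = lga_fit(series, ou2d)
    # the naive fit is systematically deflated under smoothing
    assert naive.alpha_hat[0] < result.alpha_hat[0]
    assert naive.alpha_hat[2] < result.alpha_hat[2]


def test_sklearn_fit_api(sim1d, ou1d):
    series = sim1d(0.5, n=4_000, seed=13)
    est = ConvolutionLeastSquares(model=ou1d, rho_bar=100.0)
    assert clone(est).get_params()["rho_bar"] == 100.0
    est.fit(series)
    assert est.alpha_hat_.shape == (1,)
    assert est.beta_hat_.shape == (2,)
    assert est.h1_value_ <= 0.0
    naive = LGAEstimator(model=ou1d).fit(series)
    assert naive.result_.method == "lga"
    with pytest.raises(ValueError):
        ConvolutionLeastSquares(model=None).fit(series)
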