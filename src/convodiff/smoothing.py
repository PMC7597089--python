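"""Smoothing-parameter estimation and the test for smoothed observation.

The estimator inverts the strictly decreasing population ratio of full to
reduced quadratic variation axis by axis, clamping ratios outside the
invertible range to the boundary of the parameter box.  The test statistic

    T = sqrt(3 / (2 * sum (dXbar_k)^4)) * (sum one-step sq - sum two-step sq)

is asymptotically standard normal under direct observation (rho = 0) and
diverges to -infinity under smoothing, so the rejection region for
H0: rho_i = 0 against H1: rho_i > 0 is the lower Gaussian tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .kernel import DEFAULT_RHO_BAR, ratio_R_inverse, ratio_R_min
from .qv import compute_qv_stats
from .series import ConvObsSeries, as_series

__all__ = [
    "SmoothingEstimate",
    "SmoothnessTestResult",
    "SmoothingEstimator",
    "SmoothnessTest",
    "estimate_rho",
    "smoothness_test",
]


@dataclass(frozen=True)
class SmoothingEstimate:
    """Per-axis QV ratio and smoothing-parameter estimate."""

    ratio: np.ndarray
    rho_hat: np.ndarray
    rho_bar: float

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio.tolist(),
            "rho_hat": self.rho_hat.tolist(),
            "rho_bar": self.rho_bar,
        }


@dataclass(frozen=True)
class SmoothnessTestResult:
    """Per-axis test statistic, lower-tail p-value and decision."""

    statistic: np.ndarray
    p_value: np.ndarray
    alpha_sig: float
    reject: np.ndarray

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic.tolist(),
            "p_value": self.p_value.tolist(),
            "alpha_sig": self.alpha_sig,
            "reject": self.reject.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class SmoothingEstimator(BaseEstimator):
    """Estimate the moving-average window width of each axis from QV ratios.

    Parameters
    ----------
    rho_bar : upper bound of the parameter box ``[0, rho_bar]`` (must exceed 2).
    h : sampling step used when ``fit`` receives a plain array (the ratio is
        scale-free, so ``h`` only documents the series).

    Attributes (after ``fit``)
    --------------------------
    ratio_ : per-axis sample full/reduced QV ratio ``R_n``.
    rho_hat_ : per-axis estimate; 0 where ``R_n >= 1``, ``rho_bar`` where
        ``R_n <= ratio_R_min(rho_bar)``, the ratio inverse in between.
    """

    def __init__(self, rho_bar: float = DEFAULT_RHO_BAR, h: float = 1.0):
        self.rho_bar = rho_bar
        self.h = h

    def fit(self, X, y=None):
        series = as_series(X, self.h)
        est = estimate_rho(series, self.rho_bar)
        self.ratio_ = est.ratio
        self.rho_hat_ = est.rho_hat
        self.n_features_in_ = series.d
        self.result_ = est
        return self

    def transform(self, X):
        """Return the fitted estimate (stateless transform for pipelines)."""
        return self.rho_hat_


class SmoothnessTest(BaseEstimator):
    """Test H0: axis observed directly vs H1: axis smoothed, per axis.

    Attributes after ``fit``: ``statistic_``, ``p_value_`` (lower tail),
    ``reject_`` (``statistic_ < Phi^{-1}(alpha_sig)``).  p-values are reported
    per axis with no multiplicity correction.
    """

    def __init__(self, alpha_sig: float = 0.05, h: float = 1.0):
        self.alpha_sig = alpha_sig
        self.h = h

    def fit(self, X, y=None):
        series = as_series(X, self.h)
        res = smoothness_test(series, self.alpha_sig)
        self.statistic_ = res.statistic
        self.p_value_ = res.p_value
        self.reject_ = res.reject
        self.n_features_in_ = series.d
        self.result_ = res
        return self


def estimate_rho(
    series: ConvObsSeries, rho_bar: float = DEFAULT_RHO_BAR
) -> SmoothingEstimate:
    """Invert the sample QV ratio into a smoothing-parameter estimate per axis.

    Ratios at or above 1 map to 0 (direct observation); ratios at or below the
    infimum of the population ratio map to ``rho_bar``.  A constant axis
    (zero reduced QV) is an error naming the axis.
    """
    if not rho_bar > 2.0:
        raise ValueError("rho_bar must exceed 2")
    stats = compute_qv_stats(series)
    lo = ratio_R_min(rho_bar)
    ratio = np.empty(series.d)
    rho_hat = np.empty(series.d)
    for i in range(series.d):
        if stats.reduced_qv[i] == 0.0:
            raise ZeroDivisionError(
                f"axis {i}: reduced quadratic variation is zero (constant axis?)"
            )
        r = stats.full_qv[i] / stats.reduced_qv[i]
        ratio[i] = r
        if r >= 1.0:
            rho_hat[i] = 0.0
        elif r <= lo:
            rho_hat[i] = rho_bar
        else:
            rho_hat[i] = ratio_R_inverse(r, rho_bar)
    return SmoothingEstimate(ratio=ratio, rho_hat=rho_hat, rho_bar=rho_bar)


def smoothness_test(
    series: ConvObsSeries, alpha_sig: float = 0.05
) -> SmoothnessTestResult:
    """Per-axis lower-tail Gaussian test of H0: rho_i = 0.

    ``T_i = sqrt(3 / (2 S4_i)) * (S2_i - S2red_i)`` with ``S2`` the sum of
    squared one-step increments, ``S2red`` the even-index two-step version and
    ``S4`` the quartic sum (the ``n h`` normalisations cancel).
    """
    if not 0.0 < alpha_sig < 1.0:
        raise ValueError("alpha_sig must lie in (0, 1)")
    stats = compute_qv_stats(series)
    if np.any(stats.quartic_sum <= 0.0):
        bad = int(np.argmin(stats.quartic_sum))
        raise ZeroDivisionError(f"axis {bad}: zero quartic sum (constant axis?)")
    norm_factor = stats.n * stats.h
    t = np.sqrt(3.0 / (2.0 * stats.quartic_sum)) * (
        (stats.full_qv - stats.reduced_qv) * norm_factor
    )
    p = norm.cdf(t)
    crit = norm.ppf(alpha_sig)
    return SmoothnessTestResult(
        statistic=t, p_value=p, alpha_sig=alpha_sig, reject=t < crit
    )
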