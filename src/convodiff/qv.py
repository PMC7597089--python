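"""Sample quadratic-variation statistics of observed series.

Full QV uses one-step increments; the reduced QV uses two-step increments at
even indices only.  Both are normalised by ``n * h`` (not by their number of
summands), so their population ratio is the invertible function of the
smoothing parameter provided by :mod:`convodiff.kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import ConvObsSeries

__all__ = [
    "QVStats",
    "compute_qv_stats",
    "realised_volatility_subsampled",
    "rv_profile",
]


@dataclass(frozen=True)
class QVStats:
    """Per-axis quadratic-variation summaries.

    ``full_qv[i] = (1/(n h)) sum_k (dXbar_k^i)^2`` over one-step increments,
    ``reduced_qv[i]`` the same over even-index two-step increments, and
    ``quartic_sum[i] = sum_k (dXbar_k^i)^4`` (unnormalised; it feeds the
    smoothness test statistic).
    """

    full_qv: np.ndarray
    reduced_qv: np.ndarray
    quartic_sum: np.ndarray
    n: int
    h: float


def compute_qv_stats(series: ConvObsSeries) -> QVStats:
    """Exact full/reduced QV and quartic sums of a series (requires n >= 4)."""
    n = series.n
    if n < 4:
        raise ValueError(f"need at least 4 sampling intervals, got n={n}")
    values = series.values
    diffs = np.diff(values, axis=0)
    norm = n * series.h
    full = np.sum(diffs**2, axis=0) / norm
    # even-index two-step increments: Xbar_{2k} - Xbar_{2k-2}, 2 <= 2k <= n
    even = values[0 : 2 * (n // 2) + 1 : 2]
    reduced = np.sum(np.diff(even, axis=0) ** 2, axis=0) / norm
    quartic = np.sum(diffs**4, axis=0)
    return QVStats(full_qv=full, reduced_qv=reduced, quartic_sum=quartic,
                   n=n, h=series.h)


def realised_volatility_subsampled(series: ConvObsSeries, axis: int, k: int) -> float:
    """Realised volatility at subsampling frequency ``k``.

    ``RV_k = sum_{i=1}^{floor(n/k)} (Y_{ik} - Y_{(i-1)k})^2`` for the chosen
    axis; ``RV_1`` equals ``n h`` times the full QV.
    """
    if not 1 <= k <= series.n:
        raise ValueError(f"k must be in [1, n={series.n}], got {k}")
    y = series.axis(axis)
    sub = y[0 : (series.n // k) * k + 1 : k]
    return float(np.sum(np.diff(sub) ** 2))


def rv_profile(series: ConvObsSeries, axis: int, k_max: int) -> pd.DataFrame:
    """Table of ``(k, RV_k)`` for ``k = 1..k_max`` (the smoothing diagnostic).

    A smoothed observation shows RV increasing in ``k`` up to about the window
    width, the opposite of additive microstructure noise.
    """
    if not 1 <= k_max <= series.n:
        raise ValueError(f"k_max must be in [1, n={series.n}], got {k_max}")
    ks = np.arange(1, k_max + 1)
    rvs = [realised_volatility_subsampled(series, axis, int(k)) for k in ks]
    return pd.DataFrame({"k": ks, "rv": rvs})
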