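"""Observed-series container and delimited-text I/O.

A :class:`ConvObsSeries` holds the regularly sampled (possibly smoothed)
observations ``Xbar_{i h}, i = 0..n`` as an ``(n+1, d)`` array together with
the sampling step ``h``.  The on-disk format is a plain CSV with a header
``t,x1,...,xd`` and one row per observation; writing then reading restores the
values bitwise (shortest-roundtrip float formatting).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConvObsSeries", "read_series", "write_series", "read_mat_series"]


@dataclass
class ConvObsSeries:
    """Regularly sampled observations with step ``h``.

    ``values`` has shape ``(n+1, d)``: ``n`` sampling intervals, ``d`` axes.
    """

    values: np.ndarray
    h: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2 or values.shape[0] < 2:
            raise ValueError("values must be an (n+1, d) array with n >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("series contains missing or non-finite entries")
        if not self.h > 0:
            raise ValueError(f"h must be positive, got {self.h}")
        self.values = values

    @property
    def n(self) -> int:
        """Number of sampling intervals (rows minus one)."""
        return self.values.shape[0] - 1

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.h

    def axis(self, i: int) -> np.ndarray:
        if not 0 <= i < self.d:
            raise ValueError(f"axis {i} out of range for d={self.d}")
        return self.values[:, i]


def as_series(data, h: float | None = None) -> ConvObsSeries:
    """Coerce an array or :class:`ConvObsSeries` to a series (``h`` for arrays)."""
    if isinstance(data, ConvObsSeries):
        return data
    if h is None:
        raise ValueError("h must be supplied when passing a plain array")
    return ConvObsSeries(np.asarray(data, dtype=float), h)


def write_series(series: ConvObsSeries, path: str | os.PathLike) -> None:
    """Write a series as CSV ``t,x1,...,xd`` at full float precision."""
    cols = {"t": series.times}
    for j in range(series.d):
        cols[f"x{j + 1}"] = series.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_series(path: str | os.PathLike, h: float) -> ConvObsSeries:
    """Read a delimited numeric table back into a series.

    The first column is treated as a time column and dropped when its header is
    ``t`` (the writer's format); every remaining column is one observation axis.
    """
    if h is None or not h > 0:
        raise ValueError("a positive sampling step h is required")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty series file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed series file: {path}") from exc
    if df.shape[0] < 2:
        raise ValueError(f"series file {path} has fewer than 2 rows")
    if df.columns[0].strip().lower() == "t":
        df = df.iloc[:, 1:]
    if df.shape[1] == 0:
        raise ValueError(f"series file {path} has no observation columns")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric cells in series file {path}")
    return ConvObsSeries(values.astype(float), h)


def read_mat_series(
    path: str | os.PathLike,
    h: float,
    key: str | None = None,
    max_axes: int | None = None,
) -> ConvObsSeries:
    """Read a numeric matrix from a MAT container as a series (optional input).

    Picks the first 2-D numeric variable (or ``key``), orients it with time
    along rows, and keeps the first ``max_axes`` columns when given.  No
    detrending or rescaling is applied.
    """
    from scipy.io import loadmat  # lazy: only needed for external recordings

    mat = loadmat(path)
    if key is None:
        candidates = [
            k
            for k, v in mat.items()
            if not k.startswith("__")
            and isinstance(v, np.ndarray)
            and v.ndim == 2
            and np.issubdtype(v.dtype, np.number)
        ]
        if not candidates:
            raise ValueError(f"no numeric 2-D variable found in {path}")
        key = candidates[0]
    values = np.asarray(mat[key], dtype=float)
    if values.shape[0] < values.shape[1]:
        values = values.T
    if max_axes is not None:
        values = values[:, :max_axes]
    return ConvObsSeries(values, h)
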