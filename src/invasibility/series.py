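"""Abundance time series: container, CSV round-trip, resampling.

A series is a set of integer abundances at equally spaced times. For
parameter inference the sampling interval must equal the environmental
dwell time τ, since the formulae are defined through moments of the
abundance change over one dwell period; :func:`resample` thins a finer
series to that spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceSeries", "read_series", "write_series", "resample"]

_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class AbundanceSeries:
    """Equally spaced integer abundances.

    times are in generations (or years, for the tree model); counts are
    nonnegative integers.
    """

    times: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if times.ndim != 1 or counts.ndim != 1 or len(times) != len(counts):
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError("a series needs at least two samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(steps - steps[0]) > _SPACING_RTOL * abs(steps[0])):
            bad = int(np.argmax(np.abs(steps - steps[0]) > _SPACING_RTOL * abs(steps[0])))
            raise ValueError(
                f"sampling interval is not constant (first offending step after "
                f"sample index {bad + 1})"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def dt(self) -> float:
        """Sampling interval (must equal the dwell time τ for inference)."""
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


def read_series(path) -> AbundanceSeries:
    """Read a `t,n` CSV (header required) into an :class:`AbundanceSeries`.

    Malformed rows are rejected with their 1-based file line number;
    non-constant time spacing names the offending line.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if list(df.columns[:2]) != ["t", "n"]:
        raise ValueError(f"{path}: expected header 't,n', got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    t = pd.to_numeric(df["t"], errors="coerce").to_numpy()
    n = pd.to_numeric(df["n"], errors="coerce").to_numpy()
    for col, vals in (("t", t), ("n", n)):
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(f"{path}: malformed value in column '{col}' at line {bad[0] + 2}")
    neg = np.flatnonzero(n < 0)
    if neg.size:
        raise ValueError(f"{path}: negative count at line {neg[0] + 2}")
    steps = np.diff(t)
    if len(steps) and np.any(np.abs(steps - steps[0]) > _SPACING_RTOL * abs(steps[0])):
        bad0 = int(np.argmax(np.abs(steps - steps[0]) > _SPACING_RTOL * abs(steps[0])))
        raise ValueError(f"{path}: non-constant time spacing at line {bad0 + 3}")
    return AbundanceSeries(times=t, counts=np.rint(n).astype(np.int64))


def write_series(series: AbundanceSeries, path) -> None:
    """Write a series as a `t,n` CSV."""
    pd.DataFrame({"t": series.times, "n": series.counts}).to_csv(path, index=False)


def resample(series: AbundanceSeries, tau: float) -> AbundanceSeries:
    """Thin a series to sampling interval τ (must be an integer multiple of dt)."""
    ratio = tau / series.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise ValueError(
            f"target interval {tau} is not an integer multiple of the series "
            f"interval {series.dt}"
        )
    if k == 1:
        return series
    return AbundanceSeries(times=series.times[::k], counts=series.counts[::k])
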