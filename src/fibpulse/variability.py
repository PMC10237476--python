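"""Overall and high-frequency variability statistics for FIB concentration series.

The central statistic is the normalized adjacent-sample difference

    delta_i(t) = |c(t + i) - c(t)| / mu

where ``i`` is the sampling interval and ``mu`` the mean concentration
over the entire series.  A mean delta of 1 means consecutive samples
differ, on average, by the whole-event mean concentration -- the
hallmark of 'patchy' FIB behavior.  Downsampling the base series to
coarser intervals (every possible start offset) shows how apparent
variability grows with the sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .timeseries_io import FIBSeries


@dataclass
class DeltaSeries:
    """Adjacent-sample normalized differences at one sampling interval."""

    interval_minutes: float
    deltas: np.ndarray
    mu: float

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.deltas))

    @property
    def max_delta(self) -> float:
        return float(np.max(self.deltas))

    @property
    def min_delta(self) -> float:
        return float(np.min(self.deltas))


@dataclass
class DownsampleResult:
    """Summary of delta across all start-offset versions of a downsampled series."""

    interval_minutes: float
    offsets: int
    per_offset_means: np.ndarray

    @property
    def mean_of_means(self) -> float:
        return float(np.mean(self.per_offset_means))

    @property
    def std_of_means(self) -> float:
        if len(self.per_offset_means) < 2:
            return 0.0
        return float(np.std(self.per_offset_means, ddof=1))


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two samples for a CV")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean series")
    return float(values.std(ddof=1) / mean)


def delta_series(values, interval_minutes: float) -> DeltaSeries:
    """Normalized absolute differences between adjacent samples.

    ``values`` must already lie on a regular grid with spacing
    ``interval_minutes`` and have censored samples substituted.  The
    normalizing mean is taken over the entire input series.
    """
    if isinstance(values, FIBSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two samples to form adjacent differences")
    mu = float(values.mean())
    if mu == 0:
        raise ValueError("delta undefined for zero-mean series")
    deltas = np.abs(np.diff(values)) / mu
    return DeltaSeries(interval_minutes=interval_minutes, deltas=deltas, mu=mu)


def downsample_delta(
    values, interval_minutes: float, base_interval_minutes: float = 30.0
) -> DownsampleResult:
    """Mean delta across every start-offset version of a downsampled series.

    Resampling a 30-min series to an interval of ``k`` base steps yields
    ``k`` candidate subseries (one per start offset); each contributes
    one mean delta, with the normalizing mean recomputed from that
    subseries.  Returned are all per-offset means; ``mean_of_means`` and
    ``std_of_means`` summarize them.
    """
    if isinstance(values, FIBSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    step = interval_minutes / base_interval_minutes
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError(
            f"interval {interval_minutes} must be an integer multiple of the "
            f"base interval {base_interval_minutes}"
        )
    step = int(round(step))
    means = []
    for offset in range(step):
        sub = values[offset::step]
        if len(sub) < 2:
            continue
        means.append(delta_series(sub, interval_minutes).mean_delta)
    if not means:
        raise ValueError("no offset yields at least two samples at this interval")
    return DownsampleResult(
        interval_minutes=interval_minutes,
        offsets=len(means),
        per_offset_means=np.asarray(means),
    )


def status_change_counts(flags) -> int:
    """Number of adjacent-sample pairs whose boolean status differs.

    Applied to detection status (above/below LOD) and to regulatory
    exceedance status.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) < 2:
        return 0
    return int(np.sum(flags[1:] != flags[:-1]))


def unchanged_concentration_count(values) -> int:
    """Number of adjacent-sample pairs with exactly equal concentration.

    MPN concentrations are discrete, so exact repeats are meaningful.
    """
    if isinstance(values, FIBSeries):
        values = values.values
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0
    return int(np.sum(values[1:] == values[:-1]))


def partial_autocorrelation(values, max_lag: int) -> dict:
    """Partial autocorrelation with a +/-1.96/sqrt(n) significance band.

    Uses the Levinson-Durbin recursion on the (biased) sample
    autocorrelations; the band is the large-sample white-noise null.
    Returns lags 1..max_lag with a boolean significance flag per lag.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n <= max_lag + 2:
        raise ValueError("series too short for the requested number of lags")
    if np.ptp(values) == 0:
        raise ValueError("partial autocorrelation undefined for a constant series")
    coeffs = _sm_pacf(values, nlags=max_lag, method="ldb")[1:]
    band = 1.96 / np.sqrt(n)
    return {
        "lags": np.arange(1, max_lag + 1),
        "pacf": coeffs,
        "band": band,
        "significant": np.abs(coeffs) > band,
    }
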