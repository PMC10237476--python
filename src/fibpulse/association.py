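"""Screening of FIB-environment relationships.

Monotonic association is measured with Spearman's rank correlation;
delayed driver effects are probed by correlating the FIB series against
environmental observations shifted up to three hours back in time, and
for each variable only the lag with the largest-magnitude correlation is
retained for modeling.  Grouped comparisons (day/night, high/low tide,
cloud category) use the Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Lags probed, in minutes (30-min grid, up to three hours).
DEFAULT_LAGS = (0, 30, 60, 90, 120, 150, 180)

#: Variables excluded from the temporal-lag search (purely clock-derived).
LAG_EXEMPT = ("daytime", "hours_from_noon")


@dataclass
class LagCorrelation:
    """Spearman correlation between one variable and FIB at each probed lag."""

    variable: str
    lags: tuple
    rho: np.ndarray
    p: np.ndarray

    @property
    def best_lag(self) -> int:
        finite = np.isfinite(self.rho)
        if not finite.any():
            raise ValueError(f"{self.variable}: no finite correlation at any lag")
        mags = np.where(finite, np.abs(self.rho), -np.inf)
        # ties broken toward the smaller lag (argmax returns first max)
        return int(self.lags[int(np.argmax(mags))])


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant series")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def shift_by_lag(env: pd.Series, lag_minutes: int, interval_minutes: float) -> pd.Series:
    """Shift an environmental series so row t holds its value lag minutes earlier."""
    steps = lag_minutes / interval_minutes
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"lag {lag_minutes} min is not a multiple of the {interval_minutes} min grid"
        )
    return env.shift(int(round(steps)))


def cross_correlation(
    fib: pd.Series,
    env: pd.Series,
    lags=DEFAULT_LAGS,
    interval_minutes: float | None = None,
    variable: str | None = None,
    min_overlap: int = 10,
) -> LagCorrelation:
    """Spearman correlation between FIB and a lagged environmental series.

    At lag L the environmental value observed L minutes BEFORE each FIB
    sample is paired with that sample; rows lost to the shift (or with
    missing values) are dropped pairwise.
    """
    if interval_minutes is None:
        step = fib.index[1] - fib.index[0]
        interval_minutes = step / pd.Timedelta(minutes=1)
    rhos, ps = [], []
    for lag in lags:
        shifted = shift_by_lag(env, lag, interval_minutes)
        pair = pd.concat([fib, shifted], axis=1, keys=["fib", "env"]).dropna()
        if len(pair) < min_overlap:
            raise ValueError(f"lag {lag}: only {len(pair)} overlapping samples")
        try:
            rho, p = spearman(pair["fib"].to_numpy(), pair["env"].to_numpy())
        except ValueError:
            # constant over the overlap window: no rank correlation defined
            rho, p = np.nan, np.nan
        rhos.append(rho)
        ps.append(p)
    return LagCorrelation(
        variable=variable or str(env.name),
        lags=tuple(lags),
        rho=np.asarray(rhos),
        p=np.asarray(ps),
    )


def select_lag(corr: LagCorrelation) -> tuple[str, int]:
    """The lag with the largest |rho|; ties break toward the smaller lag."""
    return corr.variable, corr.best_lag


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value on k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    if any(len(s) < 2 for s in samples):
        import warnings

        warnings.warn("a group has fewer than 2 members", stacklevel=2)
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def screen_variables(
    fib_log: pd.Series,
    env_frame: pd.DataFrame,
    lags=DEFAULT_LAGS,
    interval_minutes: float | None = None,
) -> dict[str, LagCorrelation]:
    """Cross-correlate every environmental column against one FIB series.

    Clock-derived variables (``daytime``, ``hours_from_noon``) are
    correlated at lag 0 only.
    """
    out = {}
    for name in env_frame.columns:
        col = env_frame[name].astype(float)
        use_lags = (0,) if name in LAG_EXEMPT else lags
        out[name] = cross_correlation(
            fib_log, col, lags=use_lags, interval_minutes=interval_minutes, variable=name
        )
    return out
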