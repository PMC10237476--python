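"""Ingest, censoring handling, and feature engineering for beach water-quality time series.

A sampling event is a regular-interval table of fecal indicator bacteria
(FIB) concentrations -- total coliforms (TC), *E. coli* (EC) and
Enterococcus (ENT), in MPN/100 mL -- alongside environmental covariates
(water temperature, salinity, chlorophyll a, turbidity, solar irradiance,
tide level, and airport meteorology).  Concentrations below the assay's
lower limit of detection (LOD) are left-censored; they arrive in the raw
CSV as ``"<10"`` cells and are flagged, then substituted with a nominal
1 MPN/100 mL before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Lower / upper limits of detection of the defined-substrate assay (MPN/100 mL).
LOD_LOWER = 10.0
LOD_UPPER = 24196.0

#: Value substituted for left-censored (below lower LOD) samples (MPN/100 mL).
SUBSTITUTE_VALUE = 1.0

#: California single-sample regulatory thresholds (MPN/100 mL).  EC uses the
#: fecal-coliform limit, the proxy used interchangeably in state practice.
THRESHOLDS = {"TC": 10000.0, "EC": 400.0, "ENT": 104.0}

INDICATORS = ("TC", "EC", "ENT")

#: Angle normal to the beach, degrees clockwise from true north.
BEACH_NORMAL_DEG = 140.0

CLOUD_CATEGORIES = ("clear", "overcast", "partly")

#: Environmental covariates carried through the pipeline (S-table naming).
ENV_COLUMNS = (
    "wtemp", "sal", "chl", "turb", "rad", "tide",
    "temp", "dtemp", "pres", "wspd", "wdir", "vis", "cloud",
)


@dataclass
class FIBSeries:
    """One indicator's concentration series with censoring metadata.

    Parameters
    ----------
    indicator : {"TC", "EC", "ENT"}
    values : ndarray
        Concentrations in MPN/100 mL on a regular timestamp grid.
    below_lod : ndarray of bool
        True where the assay reported below the lower LOD.
    timestamps : pd.DatetimeIndex
        Strictly increasing, constant interval, timezone-naive local
        standard time.
    """

    indicator: str
    values: np.ndarray
    below_lod: np.ndarray
    timestamps: pd.DatetimeIndex
    lod_lower: float = LOD_LOWER
    lod_upper: float = LOD_UPPER
    threshold: float = field(default=None)  # type: ignore[assignment]
    substitute_value: float = SUBSTITUTE_VALUE

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.threshold is None:
            self.threshold = THRESHOLDS[self.indicator]
        self.values = np.asarray(self.values, dtype=float)
        self.below_lod = np.asarray(self.below_lod, dtype=bool)
        if len(self.values) != len(self.below_lod) or len(self.values) != len(self.timestamps):
            raise ValueError("values, below_lod and timestamps must have equal length")
        _check_regular_grid(self.timestamps)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def interval_minutes(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("need at least two timestamps to infer an interval")
        step = self.timestamps[1] - self.timestamps[0]
        return step / pd.Timedelta(minutes=1)


@dataclass
class EventDataset:
    """Aligned table of FIB and environmental covariates for one sampling event.

    ``frame`` is indexed by timestamp; FIB columns are named by indicator,
    censoring flags are ``{indicator}_below_lod``, and derived columns are
    added by :func:`derive_features`.
    """

    frame: pd.DataFrame
    interval_minutes: float
    beach_normal_deg: float = BEACH_NORMAL_DEG

    def __post_init__(self) -> None:
        _check_regular_grid(self.frame.index)

    def fib(self, indicator: str) -> FIBSeries:
        """Extract one indicator as a :class:`FIBSeries`."""
        flag_col = f"{indicator}_below_lod"
        below = (
            self.frame[flag_col].to_numpy(dtype=bool)
            if flag_col in self.frame
            else np.zeros(len(self.frame), dtype=bool)
        )
        return FIBSeries(
            indicator=indicator,
            values=self.frame[indicator].to_numpy(dtype=float),
            below_lod=below,
            timestamps=self.frame.index,
        )

    def copy(self) -> "EventDataset":
        return EventDataset(self.frame.copy(), self.interval_minutes, self.beach_normal_deg)


def _check_regular_grid(index: pd.Index) -> None:
    if len(index) < 2:
        return
    if index.has_duplicates:
        raise ValueError("duplicated timestamps in grid")
    steps = np.diff(index.view("int64"))
    if (steps <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    if len(set(steps)) > 1:
        raise ValueError("timestamps must lie on a constant interval")


def _parse_fib_cell(cell) -> tuple[float, bool]:
    """Parse one FIB cell; ``"<10"`` style cells are left-censored."""
    if isinstance(cell, str):
        cell = cell.strip()
        if cell.startswith("<"):
            return float(cell[1:]), True
        try:
            return float(cell), False
        except ValueError:
            return np.nan, False
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan, False
    return float(cell), False


def read_event_csv(path, schema: dict | None = None) -> EventDataset:
    """Read a raw sampling-event CSV into an (unprocessed) :class:`EventDataset`.

    Parameters
    ----------
    path : str or file-like
        Long-format CSV, one row per timestamp, ISO-8601 timestamps;
        censored FIB cells written ``"<10"``.
    schema : dict, optional
        Maps canonical column names (``timestamp``, indicators, covariates)
        to the CSV's column headers.  Identity by default.
    """
    schema = schema or {}
    raw = pd.read_csv(path, dtype=str)
    ts_col = schema.get("timestamp", "timestamp")
    if ts_col not in raw.columns:
        raise ValueError(f"missing timestamp column {ts_col!r}")
    index = pd.DatetimeIndex(pd.to_datetime(raw[ts_col]), name="timestamp")
    if index.has_duplicates:
        raise ValueError("duplicated timestamps in input CSV")
    if not index.is_monotonic_increasing:
        raise ValueError("timestamps must be monotonically increasing")

    out = pd.DataFrame(index=index)
    for ind in INDICATORS:
        col = schema.get(ind, ind)
        if col not in raw.columns:
            continue
        parsed = [_parse_fib_cell(c) for c in raw[col]]
        out[ind] = np.array([v for v, _ in parsed], dtype=float)
        out[f"{ind}_below_lod"] = np.array([b for _, b in parsed], dtype=bool)

    for name in ENV_COLUMNS + ("daytime",):
        col = schema.get(name, name)
        if col not in raw.columns:
            continue
        if name == "cloud":
            out[name] = raw[col].astype(str).str.strip().str.lower().to_numpy()
        elif name == "daytime":
            out[name] = (
                raw[col].astype(str).str.strip().str.lower()
                .isin(("1", "true", "yes", "day"))
                .to_numpy()
            )
        else:
            out[name] = pd.to_numeric(raw[col], errors="coerce").to_numpy()

    steps = index.to_series().diff().dropna().unique()
    interval = steps.min() / np.timedelta64(1, "m") if len(steps) else np.nan
    return EventDataset(out, interval_minutes=float(interval))


def write_event_csv(ds: EventDataset, path) -> None:
    """Write an event dataset to tidy CSV (censored FIB cells as ``"<10"``)."""
    frame = ds.frame.copy()
    for ind in INDICATORS:
        flag_col = f"{ind}_below_lod"
        if ind in frame and flag_col in frame:
            vals = frame[ind].astype(object)
            vals[frame[flag_col].astype(bool)] = f"<{LOD_LOWER:g}"
            frame[ind] = vals
            frame = frame.drop(columns=[flag_col])
    frame.to_csv(path, index_label="timestamp")


def substitute_censored(fib: FIBSeries) -> FIBSeries:
    """Replace below-LOD concentrations with the nominal 1 MPN/100 mL."""
    if np.nanmax(fib.values, initial=0.0) > fib.lod_upper:
        warnings.warn(
            f"{fib.indicator}: sample above the upper LOD ({fib.lod_upper:g} MPN/100 mL)",
            stacklevel=2,
        )
    values = fib.values.copy()
    values[fib.below_lod] = fib.substitute_value
    return replace(fib, values=values)


def flag_exceedance(fib: FIBSeries) -> np.ndarray:
    """True where concentration strictly exceeds the single-sample threshold."""
    return fib.values > fib.threshold


def interpolate_missing(series: pd.Series, max_missing_frac: float = 0.20) -> pd.Series:
    """Fill missing values by linear interpolation in time.

    Interior gaps are interpolated linearly; leading/trailing gaps are
    filled with the nearest available value.  More than
    ``max_missing_frac`` missing is treated as a data-quality failure.
    """
    n_missing = int(series.isna().sum())
    if n_missing == 0:
        return series.copy()
    # the fractional guard is a data-quality check for event-length records;
    # a floor of 2 keeps short illustrative series interpolatable
    if n_missing > max(max_missing_frac * len(series), 2):
        raise ValueError(
            f"{series.name or 'series'}: {n_missing}/{len(series)} missing values "
            f"exceed the {max_missing_frac:.0%} quality guard"
        )
    method = "time" if isinstance(series.index, pd.DatetimeIndex) else "linear"
    filled = series.interpolate(method=method, limit_direction="both")
    filled = filled.ffill().bfill()
    return filled


def align_external(series: pd.Series, grid: pd.DatetimeIndex) -> pd.Series:
    """Align a finer-interval external series (e.g. 6-min tide) onto the event grid.

    Grid timestamps with an exactly matching source timestamp take that
    value; others are linearly interpolated in time.  The source must
    cover the full grid span.
    """
    series = series.sort_index()
    if grid.min() < series.index.min() or grid.max() > series.index.max():
        raise ValueError("external series does not cover the event grid span")
    union = series.index.union(grid)
    on_union = series.reindex(union).interpolate(method="time")
    return on_union.reindex(grid)


def derive_features(ds: EventDataset, daytime: pd.Series | None = None) -> EventDataset:
    """Add the derived modeling features to an aligned, interpolated dataset.

    Adds per-indicator ``log_{IND}`` (log10 of substituted concentration),
    ``log_chl``/``log_turb`` (log10(x+1), since both can be zero),
    ``tide_high`` (tide > 1 m above MLLW), along/offshore wind components
    relative to the beach-normal angle, cloud-category dummies, irradiance
    zeroed at night, and ``hours_from_noon`` (|clock hour - 12|, a local
    clock-noon approximation to solar noon).
    """
    out = ds.frame.copy()

    for ind in INDICATORS:
        if ind in out:
            fib = substitute_censored(ds.fib(ind))
            out[ind] = fib.values
            out[f"log_{ind}"] = np.log10(fib.values)
            out[f"{ind}_detected"] = ~fib.below_lod
            out[f"{ind}_exceedance"] = flag_exceedance(fib)

    if "chl" in out:
        out["log_chl"] = np.log10(out["chl"].astype(float) + 1.0)
    if "turb" in out:
        out["log_turb"] = np.log10(out["turb"].astype(float) + 1.0)
    if "tide" in out:
        out["tide_high"] = out["tide"].astype(float) > 1.0

    if "wspd" in out and "wdir" in out:
        owind, awind = wind_components(
            out["wspd"].to_numpy(dtype=float),
            out["wdir"].to_numpy(dtype=float),
            ds.beach_normal_deg,
        )
        out["owind"] = owind
        out["awind"] = awind

    if "cloud" in out:
        cats = out["cloud"].astype(str)
        unknown = set(cats.unique()) - set(CLOUD_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown cloud categories: {sorted(unknown)}")
        for cat in CLOUD_CATEGORIES:
            out[f"cloud_{cat}"] = (cats == cat).astype(float)

    if daytime is not None:
        out["daytime"] = daytime.reindex(out.index).astype(bool)
    elif "daytime" not in out:
        if "rad" not in out:
            raise ValueError("daytime flag must be supplied when irradiance is absent")
        out["daytime"] = out["rad"].astype(float) > 0.0
    if "rad" in out:
        out.loc[~out["daytime"].astype(bool), "rad"] = 0.0

    hours = out.index.hour + out.index.minute / 60.0
    out["hours_from_noon"] = np.abs(hours - 12.0)

    return EventDataset(out, ds.interval_minutes, ds.beach_normal_deg)


def wind_components(
    wspd: np.ndarray, wdir: np.ndarray, beach_normal_deg: float = BEACH_NORMAL_DEG
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose wind into onshore and alongshore components.

    ``wdir`` is the meteorological direction the wind blows FROM (degrees
    clockwise from true north); the flow direction is ``wdir + 180``.
    Onshore (``owind``) is positive when the wind blows landward along the
    beach-normal azimuth; alongshore (``awind``) is positive 90 degrees
    counter-clockwise of the normal.  The components conserve magnitude:
    ``owind**2 + awind**2 == wspd**2``.
    """
    toward = np.deg2rad((np.asarray(wdir, dtype=float) + 180.0) - beach_normal_deg)
    wspd = np.asarray(wspd, dtype=float)
    return wspd * np.cos(toward), wspd * np.sin(toward)
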