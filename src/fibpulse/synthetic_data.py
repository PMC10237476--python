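"""Synthetic sampling-event generator with stored ground truth.

Emulates the statistical structure the analysis pipeline assumes for a
48-hour, 30-minute-interval enclosed-beach event: semidiurnal/diurnal
tidal forcing, diel solar and temperature cycles, serially correlated
covariate noise, and FIB concentrations produced by a lagged log-linear
response with AR(2) errors, left-censored at the assay's lower LOD
(10 MPN/100 mL) with censored values substituted by 1 MPN/100 mL.

The generator is statistical emulation only -- no hydrodynamics -- and
keeps concentrations continuous rather than quantized to the discrete
MPN ladder of the defined-substrate assay.  Ground truth (coefficients,
lags, AR structure) is returned alongside each dataset so that lag
selection and coefficient recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries_io import EventDataset, LOD_LOWER, SUBSTITUTE_VALUE, derive_features

#: Principal lunar semidiurnal (M2) and lunisolar diurnal (K1) periods, hours.
M2_PERIOD_H = 12.42
K1_PERIOD_H = 23.93


@dataclass
class SyntheticTruth:
    """Generator parameters: the ground truth recovery tests compare against.

    ``beta`` maps derived-feature names to coefficients in log10 units
    per z-unit of the (standardized) covariate; ``lags`` gives each
    driver's lag in minutes.
    """

    beta: dict[str, float]
    lags: dict[str, int]
    intercept: float
    ar: tuple[float, float]
    noise_sd: float
    censor_lod: float = LOD_LOWER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        # stationarity: roots of 1 - a1 z - a2 z^2 outside the unit circle
        a1, a2 = self.ar
        if not (abs(a2) < 1 and a1 + a2 < 1 and a2 - a1 < 1):
            raise ValueError(f"AR(2) coefficients {self.ar} are not stationary")


#: Default truth: chlorophyll and turbidity load positively (sediment
#: resuspension), tide negatively at a 30-min delay (low-tide sourcing),
#: wind positively at a 60-min delay (wind-driven transport); AR(2)
#: residual structure and an ENT-like intercept giving ~10-40% censoring.
DEFAULT_TRUTH = dict(
    beta={"log_chl": 0.2, "log_turb": 0.2, "tide": -0.25, "wspd": 0.15},
    lags={"log_chl": 0, "log_turb": 0, "tide": 30, "wspd": 60},
    intercept=1.5,
    ar=(0.5, 0.2),
    noise_sd=0.5,
)

#: Per-indicator (intercept shift, spread scale): TC sits well above the
#: lower LOD with a tighter spread (so it is effectively never censored,
#: like a total-coliform record), EC intermediate, ENT the reference.
INDICATOR_ADJUST = {"TC": (0.75, 0.6), "EC": (0.25, 0.9), "ENT": (0.0, 1.0)}


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def _ar2(rng: np.random.Generator, n: int, a1: float, a2: float, innov_sd: float,
         burn: int = 200) -> np.ndarray:
    eps = rng.normal(0.0, innov_sd, size=n + burn)
    x = np.zeros(n + burn)
    for t in range(2, n + burn):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + eps[t]
    return x[burn:]


def generate_tide(
    grid: pd.DatetimeIndex,
    amplitudes: tuple[float, float] = (0.55, 0.25),
    offset: float = 0.85,
    clip: tuple[float, float] = (0.0, 2.0),
) -> np.ndarray:
    """Tide level (m above MLLW): semidiurnal + diurnal sinusoids plus offset."""
    hours = (grid - grid[0]) / pd.Timedelta(hours=1)
    hours = np.asarray(hours, dtype=float)
    a_m2, a_k1 = amplitudes
    tide = (
        offset
        + a_m2 * np.sin(2 * np.pi * hours / M2_PERIOD_H)
        + a_k1 * np.sin(2 * np.pi * hours / K1_PERIOD_H + 0.8)
    )
    return np.clip(tide, *clip)


def _solar_halfwave(grid: pd.DatetimeIndex, peak: float = 800.0) -> np.ndarray:
    """Clear-sky irradiance: daytime half-sinusoid (W/m2), zero at night."""
    hours = np.asarray(grid.hour + grid.minute / 60.0, dtype=float)
    phase = np.pi * (hours - 6.0) / 12.0  # sunrise 06:00, sunset 18:00
    rad = peak * np.sin(phase)
    rad[(hours < 6.0) | (hours > 18.0)] = 0.0
    return np.maximum(rad, 0.0)


_CLOUD_STATES = ("clear", "overcast", "partly")
# sticky 3-state Markov chain; stationary shares roughly 43/43/14%
_CLOUD_TRANSITION = np.array(
    [
        [0.92, 0.04, 0.04],
        [0.04, 0.92, 0.04],
        [0.12, 0.12, 0.76],
    ]
)


def generate_environment(
    grid: pd.DatetimeIndex, rng: np.random.Generator, noise_scale: float = 1.0
) -> pd.DataFrame:
    """Environmental covariates with diel/tidal structure and AR(1) noise.

    Ranges emulate a foggy Central-California summer harbor: water
    ~15 C, salinity ~34, chlorophyll a tens of ug/L, turbidity tens of
    NTU, winds 0-10 m/s with an afternoon sea breeze.
    """
    n = len(grid)
    hours = np.asarray(grid.hour + grid.minute / 60.0, dtype=float)
    diel = np.cos(2 * np.pi * (hours - 15.0) / 24.0)  # mid-afternoon peak

    tide = generate_tide(grid)
    rad_clear = _solar_halfwave(grid)

    cloud_idx = np.empty(n, dtype=int)
    cloud_idx[0] = rng.integers(3)
    for t in range(1, n):
        cloud_idx[t] = rng.choice(3, p=_CLOUD_TRANSITION[cloud_idx[t - 1]])
    cloud_atten = np.array([1.0, 0.35, 0.7])[cloud_idx]

    ns = noise_scale
    env = pd.DataFrame(index=grid)
    env["wtemp"] = 15.1 + 0.5 * diel + _ar1(rng, n, 0.9, 0.3 * ns)
    env["sal"] = 34.0 + 0.15 * np.sin(2 * np.pi * hours / M2_PERIOD_H) + _ar1(rng, n, 0.9, 0.15 * ns)
    # chlorophyll and turbidity: positive, right-skewed, tidally modulated
    env["chl"] = np.maximum(
        np.exp(2.5 + 0.5 * (1.0 - tide) + _ar1(rng, n, 0.85, 0.8 * ns)) - 1.0, 0.0
    )
    env["turb"] = np.maximum(
        np.exp(3.5 + 0.4 * (1.0 - tide) + _ar1(rng, n, 0.85, 0.6 * ns)) - 1.0, 0.0
    )
    env["rad"] = rad_clear * cloud_atten
    env["tide"] = tide
    env["temp"] = 15.3 + 1.5 * diel + _ar1(rng, n, 0.9, 0.4 * ns)
    env["dtemp"] = env["temp"] - 1.5 + _ar1(rng, n, 0.9, 0.3 * ns)
    env["pres"] = 1016.0 + _ar1(rng, n, 0.95, 1.0 * ns)
    env["wspd"] = np.clip(3.2 + 2.0 * diel + _ar1(rng, n, 0.8, 0.9 * ns), 0.0, 10.0)
    env["wdir"] = np.mod(300.0 + 25.0 * _ar1(rng, n, 0.9, 1.0), 360.0)
    env["vis"] = np.clip(12.0 + _ar1(rng, n, 0.9, 2.0 * ns), 0.5, 16.0)
    env["cloud"] = np.array(_CLOUD_STATES)[cloud_idx]
    return env


def generate_fib(
    features: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    interval_minutes: float,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """FIB concentrations from the lagged log-linear model with AR(2) noise.

    log10 c(t) = intercept + sum_j beta_j z_j(t - lag_j) + eps(t), where
    z_j are the standardized driver columns and eps is AR(2).  Values
    below the lower LOD are flagged censored and substituted with
    1 MPN/100 mL.  Returns (values, below_lod).
    """
    n = len(features)
    log_c = np.full(n, truth.intercept, dtype=float)
    for name, beta in truth.beta.items():
        if name not in features.columns:
            raise ValueError(f"driver {name!r} missing from feature frame")
        col = features[name].to_numpy(dtype=float)
        z = (col - col.mean()) / col.std(ddof=1)
        lag = truth.lags.get(name, 0)
        steps = int(round(lag / interval_minutes))
        if steps >= n:
            raise ValueError(f"lag {lag} min exceeds the series span")
        shifted = np.empty(n)
        # values before the record start repeat the first observation
        shifted[:steps] = z[0]
        shifted[steps:] = z[: n - steps] if steps else z
        log_c += beta * shifted
    sd = truth.noise_sd if noise_sd is None else noise_sd
    a1, a2 = truth.ar
    # innovation sd chosen so the AR(2) noise has marginal sd ~= noise_sd
    var_ratio = (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1**2))
    innov_sd = sd / np.sqrt(var_ratio)
    log_c += _ar2(rng, n, a1, a2, innov_sd)
    conc = 10.0**log_c
    below = conc < truth.censor_lod
    conc[below] = SUBSTITUTE_VALUE
    return conc, below


def generate_event(
    config: dict | None = None, seed: int = 0
) -> tuple[EventDataset, SyntheticTruth]:
    """Generate a full synthetic sampling event plus its ground truth.

    Defaults to a 48-hour, 30-minute grid (N = 96) starting 08:00 local
    standard time, the same three indicators sharing drivers but with
    indicator-specific intercepts (TC high enough that no sample is
    censored, mirroring a never-censored indicator).  ``config`` keys:
    ``n`` (grid points), ``interval_minutes``, ``start``, ``truth``
    (overrides for :data:`DEFAULT_TRUTH`), ``noise_scale``, ``sprint``
    (bool: append a nested 1-min block).
    """
    config = dict(config or {})
    interval = float(config.get("interval_minutes", 30.0))
    n = int(config.get("n", 96))
    start = pd.Timestamp(config.get("start", "2022-08-01 08:00"))
    grid = pd.date_range(start, periods=n, freq=pd.Timedelta(minutes=interval))

    truth_kwargs = {**DEFAULT_TRUTH, **config.get("truth", {})}
    truth = SyntheticTruth(seed=seed, **truth_kwargs)

    rng = np.random.default_rng(seed)
    env = generate_environment(grid, rng, noise_scale=float(config.get("noise_scale", 1.0)))

    features = env.copy()
    features["log_chl"] = np.log10(features["chl"] + 1.0)
    features["log_turb"] = np.log10(features["turb"] + 1.0)

    frame = env.copy()
    # ENT follows the truth exactly; EC and TC share the same drivers with
    # higher intercepts and tighter spreads, and independent noise streams.
    for ind in ("TC", "EC", "ENT"):
        shift, scale = INDICATOR_ADJUST[ind]
        ind_truth = SyntheticTruth(
            beta={k: v * scale for k, v in truth.beta.items()},
            lags=truth.lags,
            intercept=truth.intercept + shift,
            ar=truth.ar,
            noise_sd=truth.noise_sd * scale,
            seed=seed,
        )
        values, below = generate_fib(features, ind_truth, rng, interval)
        frame[ind] = values
        frame[f"{ind}_below_lod"] = below

    ds = EventDataset(frame, interval_minutes=interval)
    ds = derive_features(ds)
    return ds, truth


def generate_sprint(
    config: dict | None = None, seed: int = 0, n: int = 31, sub_grid_noise: float = 0.5
) -> tuple[EventDataset, SyntheticTruth]:
    """Nested 1-minute 'sprint' block sharing the event generator.

    Noise on the 1-min sub-grid is scaled down (``sub_grid_noise``) so
    that adjacent-sample variability grows with sampling interval, the
    pattern the downsampling analysis probes.  Driver lags collapse to
    zero: over a half-hour window a 30-60 min lagged driver is
    indistinguishable from its instantaneous value.
    """
    config = dict(config or {})
    config.update(n=n, interval_minutes=1.0, start=config.get("start", "2022-08-02 11:00"))
    truth_over = dict(DEFAULT_TRUTH, **config.get("truth", {}))
    truth_over["noise_sd"] = truth_over["noise_sd"] * sub_grid_noise
    truth_over["lags"] = {k: 0 for k in truth_over["lags"]}
    config["truth"] = truth_over
    return generate_event(config, seed=seed)
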