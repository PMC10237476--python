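"""Orchestrate ingest -> features -> variability -> association -> modeling.

One :func:`run_all` call takes a raw or synthetic event dataset through
every analysis stage and writes a structured, reproducible report
bundle: the processed CSV with derived columns, per-indicator
variability and association JSON, per-indicator hurdle-model JSON, and
a human-readable plain-text summary.  Every pruning decision (lag
choice, permutation-importance removal, VIF removal) is logged, since
that trail is the scientific audit record of the descriptive models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, hurdle_model, timeseries_io, variability
from .timeseries_io import EventDataset, INDICATORS

logger = logging.getLogger("fibpulse")

#: Downsampling intervals probed, minutes (base grid 30 min up to daily).
DEFAULT_INTERVALS = (30, 60, 120, 180, 360, 720, 1440)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: str | None = None
    indicators: tuple = INDICATORS
    intervals: tuple = DEFAULT_INTERVALS
    lags: tuple = association.DEFAULT_LAGS
    max_pacf_lag: int = 12
    seed: int = 0
    out_dir: str = "fibpulse_out"
    schema: dict = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def summarize_fib(ds: EventDataset, indicator: str) -> dict:
    """Event-level summary for one indicator (sample count, exceedances,
    censoring, mean/max/std, CV, mean and range of the adjacent-sample
    delta statistic)."""
    fib = timeseries_io.substitute_censored(ds.fib(indicator))
    exceed = timeseries_io.flag_exceedance(fib)
    delta = variability.delta_series(fib.values, ds.interval_minutes)
    return {
        "indicator": indicator,
        "n": len(fib),
        "exceedances": int(exceed.sum()),
        "below_lod": int(fib.below_lod.sum()),
        "mean": float(fib.values.mean()),
        "max": float(fib.values.max()),
        "std": float(fib.values.std(ddof=1)),
        "cv": variability.coefficient_of_variation(fib.values),
        "mean_delta": delta.mean_delta,
        "delta_range": [delta.min_delta, delta.max_delta],
    }


def variability_report(ds: EventDataset, indicator: str, config: RunConfig) -> dict:
    """Variability block: summary stats, downsampling curve, status-change
    counts and partial autocorrelation for one indicator."""
    fib = timeseries_io.substitute_censored(ds.fib(indicator))
    exceed = timeseries_io.flag_exceedance(fib)
    detected = ~fib.below_lod

    downsample = {}
    for interval in config.intervals:
        res = variability.downsample_delta(fib.values, interval, ds.interval_minutes)
        downsample[str(interval)] = {
            "offsets": res.offsets,
            "mean_of_means": res.mean_of_means,
            "std_of_means": res.std_of_means,
        }

    log_values = np.log10(fib.values)
    pacf = variability.partial_autocorrelation(log_values, config.max_pacf_lag)
    return {
        "summary": summarize_fib(ds, indicator),
        "downsample": downsample,
        "detection_status_changes": variability.status_change_counts(detected),
        "exceedance_status_changes": variability.status_change_counts(exceed),
        "unchanged_concentration_pairs": variability.unchanged_concentration_count(fib.values),
        "pacf": {
            "lags": pacf["lags"],
            "coefficients": pacf["pacf"],
            "band": pacf["band"],
            "significant": pacf["significant"],
        },
    }


def association_report(ds: EventDataset, indicator: str, config: RunConfig) -> dict:
    """Association block: variable x lag Spearman matrix, selected lags,
    and Kruskal-Wallis group comparisons (day/night, tide, cloud)."""
    frame = ds.frame
    fib_log = frame[f"log_{indicator}"]
    features = [f for f in hurdle_model.MODEL_FEATURES if f in frame.columns]
    corrs = association.screen_variables(
        fib_log, frame[features].astype(float), lags=config.lags,
        interval_minutes=ds.interval_minutes,
    )
    matrix = {
        name: {
            "lags": list(c.lags),
            "rho": c.rho,
            "p": c.p,
            "best_lag": c.best_lag,
        }
        for name, c in corrs.items()
    }
    groups = {}
    for label, col in (("daytime", "daytime"), ("tide_high", "tide_high"), ("cloud", "cloud")):
        if col in frame.columns:
            h, p = association.kruskal_wallis(
                frame[indicator].to_numpy(dtype=float), frame[col].to_numpy()
            )
            groups[label] = {"h": h, "p": p}
    return {"correlations": matrix, "group_comparisons": groups}


def model_report(ds: EventDataset, indicator: str, config: RunConfig) -> dict:
    """Hurdle-model block mirroring the descriptive-model tables: per-variable
    lag / importance / coefficient / p-value, pruning logs, and metrics."""
    model = hurdle_model.fit_hurdle(ds, indicator, seed=config.seed, lags=config.lags)
    rows = {}
    for name in model.design.X.columns:
        row: dict = {"lag": model.design.lags[name]}
        if model.binary_importances is not None and name in model.binary_importances.index:
            row["importance"] = float(model.binary_importances[name])
        if name in model.conc_part.params.index:
            row["coefficient"] = float(model.conc_part.params[name])
            row["p_value"] = float(model.conc_part.pvalues[name])
        rows[name] = row
    for name, v in model.pruned_by_vif:
        logger.info("model[%s]: removed %s (VIF %.1f)", indicator, name, v)
    return {
        "indicator": indicator,
        "variables": rows,
        "intercept": {
            "coefficient": float(model.conc_part.params["const"]),
            "p_value": float(model.conc_part.pvalues["const"]),
        },
        "ar_coefficients": model.conc_part.ar_coefficients,
        "pruned_by_vif": [{"variable": n, "vif": v} for n, v in model.pruned_by_vif],
        "binary_variables": model.binary_columns,
        "metrics": model.metrics,
    }


def _summary_text(summaries: list[dict], models: dict) -> str:
    lines = ["Event summary (per indicator)", "=" * 30]
    header = f"{'':14s}" + "".join(f"{s['indicator']:>10s}" for s in summaries)
    lines.append(header)
    for key in ("n", "exceedances", "below_lod", "mean", "max", "std", "cv", "mean_delta"):
        vals = []
        for s in summaries:
            v = s[key]
            vals.append(f"{v:>10.2f}" if isinstance(v, float) else f"{v:>10d}")
        lines.append(f"{key:14s}" + "".join(vals))
    lines.append("")
    lines.append("Model metrics")
    lines.append("=" * 30)
    for ind, rep in models.items():
        m = rep["metrics"]
        acc = m["binary_accuracy"]
        lines.append(
            f"{ind}: n={m['n']} below_lod={m['n_below_lod']} "
            f"binary_acc={'-' if acc is None else format(acc, '.2f')} "
            f"conc_R2={m['concentration']['r2']:.3f} "
            f"conc_RMSE={m['concentration']['rmse']:.3f} "
            f"DW={m['concentration']['durbin_watson']:.2f} "
            f"overall_R2={m['overall']['r2']:.3f} "
            f"overall_RMSE={m['overall']['rmse']:.3f}"
        )
    return "\n".join(lines) + "\n"


def run_all(config: RunConfig, ds: EventDataset | None = None) -> dict:
    """Run every stage on a dataset (read from ``config.input_path`` if not
    given) and write the report bundle under ``config.out_dir``.

    Returns the in-memory report dict with keys ``summary``,
    ``variability``, ``association`` and ``models``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if ds is None:
            if config.input_path is None:
                raise ValueError("either a dataset or config.input_path is required")
            logger.info("stage=ingest path=%s", config.input_path)
            ds = timeseries_io.read_event_csv(config.input_path, schema=config.schema)
            for col in ds.frame.columns:
                if ds.frame[col].dtype.kind == "f" and ds.frame[col].isna().any():
                    ds.frame[col] = timeseries_io.interpolate_missing(ds.frame[col])
            ds = timeseries_io.derive_features(ds)

        report: dict = {"seed": config.seed}
        try:
            report["summary"] = [summarize_fib(ds, i) for i in config.indicators]
            logger.info("stage=summary ok")
            report["variability"] = {
                i: variability_report(ds, i, config) for i in config.indicators
            }
            logger.info("stage=variability ok")
            report["association"] = {
                i: association_report(ds, i, config) for i in config.indicators
            }
            logger.info("stage=association ok")
            report["models"] = {
                i: model_report(ds, i, config) for i in config.indicators
            }
            logger.info("stage=model ok")
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage failed: {exc}") from exc

        timeseries_io.write_event_csv(ds, out / "processed.csv")
        for name in ("variability", "association", "models"):
            with open(out / f"{name}.json", "w") as fh:
                json.dump(_jsonable(report[name]), fh, indent=1, sort_keys=True)
        (out / "summary.txt").write_text(_summary_text(report["summary"], report["models"]))
        logger.info("stage=write ok dir=%s", out)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
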