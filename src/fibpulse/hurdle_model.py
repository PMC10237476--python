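"""Two-part (hurdle) descriptive model of FIB concentration.

Left-censored FIB series are zero-inflated: many samples sit below the
assay's lower LOD.  The hurdle model handles the two regimes separately:

* a **binary part** -- a 100-tree random-forest classifier -- predicts
  whether a sample is above the LOD, pruned by permutation feature
  importance (variables whose mean accuracy drop over five shuffles is
  not positive are discarded and the forest refit);
* a **concentration part** -- generalized least squares with AR(2)
  errors (iterative feasible GLS, five iterations) -- predicts log10
  concentration on the above-LOD samples, after iteratively removing
  the highest-VIF variable until every variance inflation factor is
  below 5.

Overall predictions are the product of the binary class (0/1) and the
concentration-part prediction; an indicator with no censored samples
uses the concentration part alone.  These are descriptive, in-sample
models intended to rank environmental drivers, not to forecast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from .association import DEFAULT_LAGS, screen_variables, shift_by_lag
from .timeseries_io import EventDataset

#: Candidate model features (derived-column names), in table order.
MODEL_FEATURES = (
    "wtemp", "sal", "log_chl", "log_turb", "rad", "tide", "tide_high",
    "temp", "dtemp", "pres", "wspd", "awind", "owind", "vis",
    "cloud_overcast", "cloud_partly", "cloud_clear",
    "daytime", "hours_from_noon",
)

VIF_THRESHOLD = 5.0
N_TREES = 100
N_SHUFFLES = 5
AR_ORDER = 2
GLS_ITERATIONS = 5


@dataclass
class LaggedDesign:
    """Per-indicator design matrix of best-lag, z-scored covariates."""

    X: pd.DataFrame
    lags: dict[str, int]
    target_binary: pd.Series
    target_conc: pd.Series
    norm_params: pd.DataFrame  # columns: mean, sd

    def subset(self, columns) -> "LaggedDesign":
        columns = list(columns)
        return LaggedDesign(
            X=self.X[columns],
            lags={k: v for k, v in self.lags.items() if k in columns},
            target_binary=self.target_binary,
            target_conc=self.target_conc,
            norm_params=self.norm_params.loc[columns],
        )


def zscore(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize columns to mean 0, sd 1 (sample sd); drop constant columns."""
    means = frame.mean()
    sds = frame.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        frame = frame.drop(columns=constant)
        means = means.drop(constant)
        sds = sds.drop(constant)
    z = (frame - means) / sds
    norm = pd.DataFrame({"mean": means, "sd": sds})
    return z, norm


def build_design(
    ds: EventDataset,
    indicator: str,
    lags=DEFAULT_LAGS,
    features=MODEL_FEATURES,
) -> LaggedDesign:
    """Assemble the modeling design matrix for one indicator.

    Each candidate covariate is cross-correlated with the log10
    concentration over the probed lags; only its best-lag version is
    kept (clock-derived variables are not lagged).  Rows lost to the
    lag shifts are dropped, then columns are z-scored.
    """
    frame = ds.frame
    present = [f for f in features if f in frame.columns]
    env = frame[present].astype(float)
    fib_log = frame[f"log_{indicator}"]
    corrs = screen_variables(fib_log, env, lags=lags, interval_minutes=ds.interval_minutes)
    usable = [n for n in present if np.isfinite(corrs[n].rho).any()]
    dropped = sorted(set(present) - set(usable))
    if dropped:
        warnings.warn(f"dropping variables with no finite correlation: {dropped}", stacklevel=2)
    present = usable
    best = {name: corrs[name].best_lag for name in present}

    shifted = pd.DataFrame(
        {
            name: shift_by_lag(env[name], best[name], ds.interval_minutes)
            for name in present
        }
    )
    mask = shifted.notna().all(axis=1)
    shifted = shifted.loc[mask]
    z, norm = zscore(shifted)
    return LaggedDesign(
        X=z,
        lags={k: best[k] for k in z.columns},
        target_binary=frame.loc[mask, f"{indicator}_detected"].astype(bool),
        target_conc=fib_log.loc[mask],
        norm_params=norm,
    )


# ---------------------------------------------------------------- binary part


def fit_binary_forest(
    X: pd.DataFrame, y: pd.Series, seed: int = 0
) -> tuple[RandomForestClassifier, float]:
    """Fit the 100-tree random-forest detection classifier.

    Bootstrap resampling per tree, Gini splits, sqrt(p) candidate
    features per split, unlimited depth; accuracy is in-sample.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class target: no binary part")
    forest = RandomForestClassifier(
        n_estimators=N_TREES,
        bootstrap=True,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
    )
    forest.fit(X, y)
    accuracy = float(forest.score(X, y))
    return forest, accuracy


def permutation_prune(
    forest: RandomForestClassifier,
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
) -> tuple[pd.DataFrame, RandomForestClassifier, pd.Series]:
    """Remove variables with non-positive permutation importance and refit.

    Importance is the mean drop in accuracy over five independent
    shuffles of one column at evaluation time (no per-shuffle refit).
    Reported importances come from the refit forest.
    """
    y = np.asarray(y, dtype=int)
    imp = permutation_importance(
        forest, X, y, n_repeats=N_SHUFFLES, random_state=seed, scoring="accuracy"
    )
    means = pd.Series(imp.importances_mean, index=X.columns)
    keep = means[means > 0].index.tolist()
    if not keep:
        keep = [means.idxmax()]
        warnings.warn(
            "permutation pruning removed every variable; keeping the single "
            f"highest-importance one ({keep[0]})",
            stacklevel=2,
        )
    X_kept = X[keep]
    refit, _ = fit_binary_forest(X_kept, y, seed=seed)
    imp2 = permutation_importance(
        refit, X_kept, y, n_repeats=N_SHUFFLES, random_state=seed, scoring="accuracy"
    )
    final = pd.Series(imp2.importances_mean, index=X_kept.columns)
    return X_kept, refit, final


# --------------------------------------------------------- concentration part


def vif(X: pd.DataFrame, variable: str) -> float:
    """Variance inflation factor of one column regressed on the rest.

    VIF_j = 1 / (1 - R2_j), with an intercept in the auxiliary
    regression; perfect collinearity returns +inf.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two variables")
    # a column constant on the modeled rows is perfectly collinear with
    # the intercept; the auxiliary R2 is then undefined
    if np.ptp(X[variable].to_numpy(dtype=float)) == 0:
        return float("inf")
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    j = list(X.columns).index(variable) + 1  # skip the constant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = variance_inflation_factor(exog, j)
    if not np.isfinite(value) or value > 1e12:
        return float("inf")
    return float(value)


def vif_prune_loop(
    X: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Iteratively drop the highest-VIF column until all VIFs are below threshold.

    Ties break toward the earlier column.  Returns the reduced design and
    the removal log as (variable, VIF-at-removal) pairs.
    """
    X = X.copy()
    removed: list[tuple[str, float]] = []
    while X.shape[1] >= 2:
        vifs = pd.Series({c: vif(X, c) for c in X.columns})
        worst = vifs.idxmax()  # first occurrence wins on ties
        if vifs[worst] < threshold:
            break
        removed.append((str(worst), float(vifs[worst])))
        X = X.drop(columns=[worst])
    return X, removed


@dataclass
class ConcentrationPart:
    """Fitted GLS-AR(2) regression of log10 concentration on the design."""

    params: pd.Series
    pvalues: pd.Series
    ar_coefficients: np.ndarray
    columns: list[str] = field(default_factory=list)
    _results: object = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = set(self.columns) - set(X.columns)
        if missing:
            raise ValueError(f"design is missing model columns: {sorted(missing)}")
        exog = sm.add_constant(X[self.columns].to_numpy(dtype=float), has_constant="add")
        return exog @ self.params.to_numpy()

    @property
    def whitened_residuals(self) -> np.ndarray:
        return np.asarray(self._results.wresid)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Coefficient confidence intervals from the final whitened fit."""
        ci = np.asarray(self._results.conf_int(alpha))
        return pd.DataFrame(ci, index=self.params.index, columns=["lower", "upper"])


def fit_gls_ar(
    X: pd.DataFrame,
    y: pd.Series,
    order: int = AR_ORDER,
    iterations: int = GLS_ITERATIONS,
) -> ConcentrationPart:
    """Iterative feasible GLS with AR(``order``) errors and a constant intercept.

    Alternates an OLS fit with re-estimation of the residual AR
    coefficients and quasi-differencing of both sides, for the given
    number of iterations.  ``order=0`` is plain ordinary least squares.
    Coefficient p-values come from t statistics on the final whitened fit.
    """
    y = pd.Series(y).astype(float)
    exog = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        vifs = {c: vif(X, c) for c in X.columns} if X.shape[1] >= 2 else {}
        bad = [c for c, v in vifs.items() if not np.isfinite(v)]
        raise ValueError(f"design matrix is singular; offending columns: {bad or 'unknown'}")
    if order == 0:
        results = sm.OLS(y.to_numpy(), exog).fit()
        rho = np.array([])
    else:
        model = sm.GLSAR(y.to_numpy(), exog, rho=order)
        results = model.iterative_fit(maxiter=iterations)
        rho = np.atleast_1d(model.rho)
    names = ["const"] + list(X.columns)
    return ConcentrationPart(
        params=pd.Series(np.asarray(results.params), index=names),
        pvalues=pd.Series(np.asarray(results.pvalues), index=names),
        ar_coefficients=rho,
        columns=list(X.columns),
        _results=results,
    )


# ------------------------------------------------------------------- assembly


@dataclass
class HurdleModel:
    """Fitted hurdle model: binary + concentration parts with pruning records."""

    indicator: str
    design: LaggedDesign
    binary_part: RandomForestClassifier | None
    binary_columns: list[str]
    binary_importances: pd.Series | None
    conc_part: ConcentrationPart
    pruned_by_vif: list[tuple[str, float]]
    metrics: dict

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return hurdle_predict(self, X)


def hurdle_predict(model: HurdleModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted log10 concentration: binary class times regression output.

    A predicted class of 0 (below LOD) forces the overall prediction to
    0 = log10 of the 1 MPN/100 mL substitute.  Without a binary part
    (never-censored indicator) the regression output is returned as-is.
    """
    conc = model.conc_part.predict(X)
    if model.binary_part is None:
        return conc
    missing = set(model.binary_columns) - set(X.columns)
    if missing:
        raise ValueError(f"design is missing binary-part columns: {sorted(missing)}")
    classes = model.binary_part.predict(X[model.binary_columns])
    return classes * conc


def model_metrics(observed, predicted, whitened_residuals=None) -> dict:
    """R2, RMSE (log10 units) and, when residuals are given, Durbin-Watson."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted must have equal length")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed series has zero variance")
    sse = float(np.sum((observed - predicted) ** 2))
    out = {
        "r2": 1.0 - sse / sst,
        "rmse": float(np.sqrt(np.mean((observed - predicted) ** 2))),
    }
    if whitened_residuals is not None:
        out["durbin_watson"] = float(durbin_watson(np.asarray(whitened_residuals)))
    return out


def fit_hurdle(
    ds: EventDataset,
    indicator: str,
    seed: int = 0,
    lags=DEFAULT_LAGS,
    features=MODEL_FEATURES,
) -> HurdleModel:
    """Fit the full hurdle model for one indicator on an event dataset.

    Below-LOD observations enter the overall (hurdle) metrics encoded as
    log10(1) = 0, matching the censored-value substitution.
    """
    design = build_design(ds, indicator, lags=lags, features=features)
    detected = design.target_binary.to_numpy(dtype=bool)

    binary_part = None
    binary_cols: list[str] = []
    binary_imp = None
    binary_acc = None
    if detected.all() or (~detected).all():
        pass  # no binary part: detection status never varies
    else:
        forest, _ = fit_binary_forest(design.X, detected.astype(int), seed=seed)
        X_kept, forest, binary_imp = permutation_prune(
            forest, design.X, detected.astype(int), seed=seed
        )
        binary_part = forest
        binary_cols = list(X_kept.columns)
        binary_acc = float(forest.score(X_kept, detected.astype(int)))

    X_conc = design.X.loc[detected]
    y_conc = design.target_conc.loc[detected]
    X_pruned, removed = vif_prune_loop(X_conc)
    conc_part = fit_gls_ar(X_pruned, y_conc)

    model = HurdleModel(
        indicator=indicator,
        design=design,
        binary_part=binary_part,
        binary_columns=binary_cols,
        binary_importances=binary_imp,
        conc_part=conc_part,
        pruned_by_vif=removed,
        metrics={},
    )

    conc_pred = conc_part.predict(design.X[X_pruned.columns].loc[detected])
    conc_metrics = model_metrics(y_conc, conc_pred, conc_part.whitened_residuals)

    overall_obs = design.target_conc.to_numpy(dtype=float).copy()
    overall_obs[~detected] = 0.0
    overall_pred = hurdle_predict(model, design.X)
    overall_metrics = model_metrics(overall_obs, overall_pred)

    model.metrics = {
        "n": int(len(design.X)),
        "n_below_lod": int((~detected).sum()),
        "binary_accuracy": binary_acc,
        "concentration": conc_metrics,
        "overall": overall_metrics,
    }
    return model
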