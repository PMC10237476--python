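# Methods

`fibpulse` analyzes high-frequency (sub-hourly) sampling events of fecal
indicator bacteria (FIB) at recreational beaches: total coliforms (TC),
*E. coli* (EC) and Enterococcus (ENT), measured in MPN/100 mL by
defined-substrate assays with a lower limit of detection (LOD) of 10 and
an upper limit of 24,196 MPN/100 mL. This note describes the statistical
model and procedure each module implements, the parameters that matter,
and the choices made where the design was genuinely open.

## Censoring and preprocessing

Concentrations below the lower LOD are left-censored. They are flagged
on ingest (cells written `"<10"`) and substituted with a nominal
1 MPN/100 mL, which makes censored samples identifiable on the raw scale
(log10 = 0) without affecting the hurdle model, whose binary part absorbs
the censored class. Exceedance of the California single-sample marine
standards (TC 10,000; ENT 104; for EC the fecal-coliform proxy limit of
400 MPN/100 mL) is a strict inequality: a sample exactly at the threshold
does not exceed it, matching the single-sample notification convention.

Interior missing values in environmental series are linearly interpolated
in time; leading/trailing gaps take the nearest available value (no
extrapolation). A quality guard rejects series with more than 20% missing
(with a floor of two values so that short illustrative series remain
usable). External series on finer grids — tide arrives at 6-minute
resolution — are aligned to the event grid by exact-timestamp match where
one exists and time-weighted linear interpolation otherwise.

Derived features: log10 FIB; log10(x+1) for chlorophyll a and turbidity
(both can be zero); `tide_high` = tide > 1 m above mean lower low water
(MLLW); wind decomposed into onshore/alongshore components about the
beach-normal azimuth (140° from true north by default) — onshore positive
when the wind blows landward along the normal, alongshore positive 90°
counter-clockwise of it; the decomposition conserves magnitude. Cloud
category becomes three dummies (clear/overcast/partly). Irradiance is
forced to 0 W/m² outside the daytime flag (supplied for real data,
irradiance > 0 for synthetic data). `hours_from_noon` uses local clock
noon, a deliberate approximation to solar noon that avoids an ephemeris
dependency; at a fixed site over 48 h the two differ by a near-constant
offset that normalization absorbs.

## Variability statistics

The coefficient of variation uses the sample standard deviation (n−1).
The high-frequency statistic is the normalized adjacent-sample
difference

    delta_i(t) = |c(t+i) − c(t)| / mu,

with `i` the sampling interval and `mu` the mean concentration of the
entire series analyzed. Both CV and delta operate on raw-scale,
substituted concentrations, not log values — the statistic is meant to
express concentration jumps relative to the event mean.

Downsampling: a 30-min series resampled to an interval of `k` base steps
yields `k` subseries, one per start offset. Each contributes one mean
delta, with `mu` recomputed from that subseries (each downsampled
record is treated as the series a coarser campaign would have
collected); the mean and standard deviation across offsets summarize
the interval. Status-change counts are adjacent-pair counts: positions
`t` where the detection (above/below LOD) or exceedance flag differs at
`t+1`; the final sample has no successor and contributes no pair.

The partial autocorrelation uses the Levinson–Durbin recursion on the
biased sample autocorrelations of the log10 series, with the
white-noise null band ±1.96/√n. On white noise roughly 5% of lags fall
outside this band by construction.

## Association screening

Monotonic association uses tie-corrected Spearman rank correlation
(large-sample p). Delayed driver effects are probed by pairing each FIB
sample with the environmental value observed 0–180 minutes earlier, on
the 30-minute grid. Rows lost to the shift are dropped pairwise. For
each variable only the lag with the largest |ρ| is retained (ties break
toward the smaller lag); the clock-derived variables `daytime` and
`hours_from_noon` are exempt from lagging. Variables that are constant
over every lag window (a cloud category never observed, say) have no
defined rank correlation; they screen as NaN and are dropped from the
modeling design with a warning. Group comparisons (day/night, high/low
tide, cloud category) use the tie-corrected Kruskal–Wallis H with a
chi-square reference on k−1 degrees of freedom.

## Hurdle model

FIB series with censored samples are zero-inflated, so concentration is
modeled in two parts.

**Binary part.** A 100-tree random-forest classifier (bootstrap
resampling per tree, Gini splits, √p candidate features per split,
unlimited depth) predicts detection (above/below LOD). Variables are
then pruned by permutation feature importance: the mean drop in
in-sample accuracy over five independent shuffles of one column,
evaluated without refitting per shuffle (the standard evaluation-time
permutation-importance algorithm). Variables whose mean importance is
not positive are removed and the forest refit; reported importances come
from the refit forest. If everything would be removed, the single
highest-importance variable is kept, with a warning. An indicator that
is never (or always) censored has no binary part.

**Concentration part.** Log10 concentration of the detected samples is
regressed on the z-scored design by feasible generalized least squares
with AR(2) errors (the `GLSAR` iterative scheme, five iterations):
ordinary least squares, Yule–Walker estimation of the residual AR
coefficients, quasi-differencing of response and regressors, refit.
Order 0 reproduces ordinary least squares exactly, which pins the
contract. Before fitting, multicollinearity is pruned iteratively: the
variable with the highest variance inflation factor (VIF = 1/(1−R²) of
that column on the rest plus intercept) is removed until every VIF is
below 5; ties break toward the earlier column and a column constant on
the modeled rows counts as infinite VIF (it is collinear with the
intercept). Coefficients with p < 0.05 on the final whitened fit are
reported significant.

**Combination and metrics.** The overall prediction is the product of
the hard binary class (0/1) and the concentration-part prediction, so a
predicted non-detect forces log10(1) = 0; never-censored indicators use
the concentration part alone. All metrics are in-sample — these are
descriptive models of one sampling event, ranking drivers rather than
forecasting — with R² = 1 − SSE/SST, RMSE in log10 units, and the
Durbin–Watson statistic on the whitened concentration-part residuals
(≈2 when the AR(2) structure is adequate). Overall metrics encode
observed below-LOD samples as 0. The probability-weighted alternative
to the hard class is deliberately not used: with in-sample binary
accuracy at or near 1 the two coincide.

## Synthetic events

The generator emulates the structure the analysis assumes for a 48-hour,
30-minute event (N = 96) at an enclosed Central-California beach in
summer: tide as semidiurnal (12.42 h) plus diurnal (23.93 h) sinusoids
offset to the 0–2 m MLLW band; a diel cycle in water/air temperature,
wind (afternoon sea breeze, 0–10 m/s around a 3.2 m/s mean) and
irradiance (daytime half-sinusoid attenuated by a sticky three-state
cloud Markov chain); right-skewed, tidally modulated chlorophyll and
turbidity; AR(1) noise on every covariate.

FIB follow a lagged log-linear response,

    log10 c(t) = intercept + Σ_j beta_j · z_j(t − lag_j) + eps(t),

with `z_j` the standardized driver, `eps` AR(2) on the log scale (the
scale the models operate on), and left-censoring below 10 MPN/100 mL
with substitution by 1. Defaults: drivers log-chlorophyll (+0.2, lag 0),
log-turbidity (+0.2, lag 0), tide (−0.25, lag 30 min), wind speed
(+0.15, lag 60 min); intercept 1.5 log10 MPN/100 mL and noise SD 0.5 for
ENT, giving a ~25% censored fraction; EC and TC share drivers with
higher intercepts and tighter spreads (scale 0.9 / 0.6), making TC
effectively never censored — which exercises the no-binary-part path —
and keeping every value below the upper LOD. Concentrations stay
continuous; quantization to the discrete MPN ladder of the assay is out
of scope. A nested 1-minute "sprint" block reuses the generator with
noise scaled down on the sub-grid and driver lags collapsed to zero
(over a half-hour window a 30–60 min lagged driver is indistinguishable
from its instantaneous value).

What the generator does **not** emulate: intermittent point-source
inputs (rain, bird loading), MPN measurement discreteness and assay
error, spatial patchiness, or hydrodynamic transport. Passing recovery
tests therefore show the estimators are correct under the assumed
model, not that the model captures every feature of real beach data.

## Verification conditions and numerical choices

- **Coefficient recovery** uses a strong-signal variant: n = 500,
  |beta| ≥ 0.3, AR(2) noise (0.5, 0.2), intercept 3.0 so censoring is
  negligible — the concentration part models detected samples only, and
  heavy censoring would truncate the response. Each true beta should
  fall inside its 95% CI in ≥90% of 100 seeds.
- **Lag recovery** requires a driver that decorrelates over the lag
  scale. A smooth near-periodic driver like tide shifted 30 minutes is
  ~0.97-correlated with itself, so no method can single out its lag;
  the recovery experiment therefore uses a single dominant stochastic
  driver (log-turbidity, AR(1)-type, beta 0.6) at a 60-minute lag,
  identified in ≥80% of 100 seeds.
- **Downsampling trend** is tested on AR-only series with slowly
  decaying correlation, AR(2) = (0.85, 0.05), because serial dependence
  must persist across the probed intervals (up to 24 base steps) and
  periodic drivers alias at half-day spacings, producing a genuine
  (and physically meaningful) dip at 12 h.
- Problem sizes: 100 seeds for recovery and trend experiments, 30
  fitted hurdle models for the censoring comparison — enough for stable
  rate estimates while keeping a full run in the low minutes on one
  core.
- Degenerate inputs: constant series raise errors in CV/PACF/Spearman;
  perfect collinearity returns an infinite VIF sentinel; a singular
  concentration design raises with the offending columns named.
- Determinism: one integer seed drives the generator, the forest and
  the permutation shuffles; repeated runs are bit-identical.

## Known limitations

- In-sample metrics overstate out-of-sample skill by design; the
  random-forest part in particular memorizes a 96-sample event
  (in-sample accuracy 1.0 is expected, not impressive).
- The per-variable best-lag screen is a marginal criterion; correlated
  drivers can swap lags between indicators.
- The substitution value (1 MPN/100 mL) is conventional; delta and CV
  on heavily censored series depend on it.
- `hours_from_noon` ignores the equation of time and longitude offset.
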