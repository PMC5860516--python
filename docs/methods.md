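# Methods

This note records the model conventions, numerical choices and synthetic-data
design behind `dhrpanel`, at the level of detail a maintainer needs to change
them safely.

## Stage 1: dynamic harmonic regression

The area-wide monthly log rate is modelled as a regression on an intercept, an
(optionally lagged) monthly temperature, and k pairs of cos/sin terms at
multiples of the annual frequency ω = 2π/12, whose coefficients evolve as
Gaussian random walks.  The state vector is (a, β, A_1, B_1, …, A_k, B_k):
intercept and temperature slope are constant states (zero innovation
variance) inside the same state vector rather than profiled out, so a single
Kalman code path covers the static and dynamic fits and their equivalence is
testable exactly.  The transition matrix is the identity; the observation
vector at month t is (1, d(t), cos(pωt), sin(pωt), …); the innovation
covariance is diagonal, with one variance shared within each cos/sin pair and
distinct across harmonics (a single shared variance is available via
`shared_rw_variance=True`).

Defaults and rationale:

- **k = 2** (annual plus semi-annual), configurable 1–5 (k ≤ 5 keeps all
  harmonics below the Nyquist frequency for monthly data).  Two harmonics are
  the minimum that can represent asymmetric winter/spring peaking.
- **Diffuse initialization** is approximated by a finite prior variance of
  10⁷ × the sample variance of y on every state.  The likelihood contributions
  of the first *d* observed innovations (d = state dimension) are excluded
  from the ML criterion so the approximation cannot dominate; the test-suite
  oracle (a dense joint-Gaussian computation, done in extended precision
  because the diffuse scale is deliberately extreme) uses the identical
  convention.
- **Estimation** maximizes the concentrated prediction-error log-likelihood:
  the common variance scale is profiled out analytically, leaving only the k
  random-walk-to-observation variance ratios, optimized by L-BFGS-B on the
  log scale from 5 deterministic starts (log₁₀ ratios −8, −5, −3, −1.5, 0)
  with objective tolerance 1e−10.  Ratio bounds are e^±(23, 6); an estimate at
  the lower bound is reported as a (near-)zero random-walk variance, not
  hidden.
- **Missing months** skip the measurement update; smoothed fitted values are
  still produced wherever the regressors exist.  Months whose lagged
  temperature is unavailable are treated as missing, never imputed.
- **R²** is the squared Pearson correlation between observed and smoothed
  fitted values (not 1 − SSE/SST, which differs for biased fits).
- **Lag handling**: a lag of L days pairs month t with the mean of the daily
  temperatures recorded L days before each calendar day of month t; the
  "1 month" lag is the plain mean of the previous calendar month (not 30
  days).  Exact ties in the lag-selection table break toward the shorter lag.
- **Trend**: by default the slow secular trend is left to the stage-2
  elapsed-time covariate; `trend=True` adds a constant-slope state to stage 1
  instead.  Either way the stage-1 curve absorbs whatever the offset needs to
  absorb — the partition between temperature, harmonics and trend does not
  change the fitted curve (the package exposes this classical identity via
  `temperature_anomaly_identity`, which refits the static model with the
  temperature's seasonal-anomaly series and verifies identical predictions).

## Stage 2: random-intercept mixed model

With the stage-1 curve entering as an offset (implicit coefficient exactly 1),
the model is a one-way random-intercept LMM.  Estimation profiles the REML
(default) or ML criterion down to a one-dimensional search over
λ = σ_b²/σ_ε² on log λ ∈ [−30, 30] (bounded Brent, xatol 1e−11), with the
boundary λ = 0 always evaluated explicitly and reported when optimal.  Given
λ, fixed effects are closed-form GLS via per-practice Sherman–Morrison
algebra, so the fit is O(N p²) regardless of panel size.  Wald standard
errors come from the GLS covariance; t and two-sided p values use residual
degrees of freedom N − p (Satterthwaite-type corrections are out of scope —
with thousands of records the difference is negligible for within-practice
covariates, and modest for practice-constant ones).  Covariates are used on
their input scale; nothing is standardized or auto-dropped.  BLUPs are the
shrunken practice means of the fixed-effect residuals, with conditional
variance σ_b²/(1 + n_j λ); prediction intervals are normal-quantile central
intervals, sorted by conditional mean.  Practices with a single observation
are allowed; their BLUPs simply shrink strongly.

## Diagnostics

- **ACF**: single overall mean, lag-0 autocovariance as denominator (both
  conventions exist in the literature; this one makes acf(0) = 1 exactly).
- **Variograms**: semivariances v_ij = ½(y_i − y_j)² over all unordered
  pairs; left-closed right-open 1-km bins up to 20 km (configurable); empty
  bins carry NaN, never zero; pairs beyond the maximum distance are discarded
  and counted.
- **Permutation envelope**: values are first detrended by an OLS linear trend
  surface in (easting, northing); the envelope is the pointwise min/max of
  the binned variograms of 99 seeded uniform permutations of the residuals
  over the locations (pointwise two-sided level ≈ 2/100 per bin).  In the
  pipeline the envelope is computed on the practice BLUPs, one value per
  location.
- **Spatiotemporal variogram**: mean semivariance per (distance bin × time
  lag 0–3 months) cell; the lag-0 column uses contemporaneous distinct-site
  pairs only, while same-site pairs at positive lags enter the 0-distance
  bin.  Computed by matrix algebra over the practices × months panel, which
  is exactly equivalent to pair enumeration (tested against a brute-force
  double loop).

## Synthetic-data generator

`gen_panel` emulates the data structure the two-stage model assumes — not any
particular real data set's magnitudes.  Defaults (log-rate scale):

- 63 practices × 55 months on a 20 × 20 km window, anchored 2002-01-01
  (months indexed 1..T; days per month follow the real Gregorian calendar,
  needed for daily→monthly temperature averaging).
- Daily temperature: annual sinusoid, mean 9.5 °C, amplitude 6.5 °C, minimum
  mid-January, iid daily noise sd 3 °C, with 31 lead-in days so lagged monthly
  means are computable.
- Area-wide path: intercept −2.0; temperature coefficient −0.04 per °C (cold
  months raise the rate; temperature carries the bulk of the seasonal signal,
  as intended for a toolkit whose point is seasonal adjustment *through*
  temperature); k = 2 harmonic pairs with initial amplitudes N(0, 0.06²) and
  N(0, 0.03²) and random-walk innovation sd 0.008 and 0.005 per month — over
  55 months the drift sd (~0.06) is comparable to the amplitude itself, so
  year-to-year cycle shapes visibly differ; area shock σ_u = 0.02.  These
  ratios were chosen once so that all hyperparameters are identifiable at
  T = 55 (much smaller observation noise lets maximum likelihood push σ_u²
  to zero and interpolate, a real weak-identification regime, not a bug).
- Practice level: covariates `time_elapsed` (month index, coefficient
  −0.0005/month, a small secular decline), plus standardized smooth spatial
  fields `income`, `employment`, `age` (coefficients 0.08, 0.05, 0.01) built
  from random low-frequency trigonometric surfaces with a white-noise nugget
  — the covariate distributions are invented plumbing, with no claim of
  fidelity to any real deprivation or demographic variable; random intercepts
  sd 0.1; residual sd 0.05.
- Residual options: iid; spatially correlated (exponential correlation, the
  simplest strictly positive-definite family, default range 5 km); or
  separable spatiotemporal (exponential in space × stationary AR(1) in time,
  default coefficient 0.6) — sufficient to exercise every diagnostic.
- Ground truth (states, seasonal path, area shocks, random intercepts,
  residual field) is always emitted next to the panel; tests never re-derive
  truth from data.  All randomness fans out from one seed via named
  substreams, so panels are bit-reproducible.

What passing tests on these panels do **not** show: robustness to
non-Gaussian outcomes, irregular calendars, covariate measurement error, or
confounding between the temperature driver and omitted seasonal factors —
the generator is correctly specified for the model by construction, so the
recovery tests validate the estimation machinery, not the model's adequacy
for any real data set.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence checks run at T = 12–24 months (dense-Gaussian
brute force is O(T³)); recovery simulations use the full 63 × 55 study shape
with 50 replicates for the mixed model and 25 replicates for lag selection
and the dynamic-vs-static comparison; envelope calibration and power use 50
replicates of 63 sites with 99 permutations; spatiotemporal-variogram null
and power checks use 25 replicates.  `scripts/acceptance.py` runs the full
pipeline once at the study shape with all five candidate lags and 99
permutations.

## Known limitations

- No forecasting interface: the DHR is used as a smoother (seasonal
  adjustment), not a predictor of future months.
- Single random intercept only — no random slopes, crossed effects or
  spatially correlated random effects; no non-Gaussian responses.
- No parametric variogram fitting or kriging; the diagnostics are purely
  empirical.
- The permutation envelope is pointwise, so with ~20 occupied bins a fully
  inside observed variogram occurs in roughly two-thirds of null replicates;
  judging a single bin excursion requires the calibration logic used in the
  test suite, not a fixed rule.
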