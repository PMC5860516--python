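# dhrpanel

Two-stage modelling of seasonally varying, spatiotemporally indexed health
outcomes — for example monthly respiratory-prescribing rates recorded at a set
of primary-care practices.  Many such outcomes peak every winter and spring,
with the size and shape of each annual cycle drifting from year to year; naive
seasonal adjustment leaves spurious correlation between consecutive months and
neighbouring practices.  `dhrpanel` separates the two kinds of variation:

**Stage 1 — area-wide seasonal trend.**  A *dynamic harmonic regression* (DHR)
for the area-wide monthly log rate Y(t),

    Y(t) = a + β d(t) + Σ_{p=1..k} [ A_{p,t} cos(pωt) + B_{p,t} sin(pωt) ] + U_t,

with ω = 2π/12, d(t) the (optionally lagged) average daily mean temperature in
month t, harmonic coefficients A_{p,t}, B_{p,t} following random walks, and
U_t ~ N(0, σ_u²).  Cast as a Gaussian state-space model, fitted by maximum
likelihood via the Kalman filter (prediction-error decomposition) and smoothed
to give the fitted seasonal curve μ̂_t.  Candidate temperature lags (0, 7, 14,
21 days, 1 month) are ranked by R², the squared correlation between observed
and fitted values; a static OLS harmonic regression provides the comparison.

**Stage 2 — residual spatiotemporal variation.**  A linear mixed model for the
practice-month log rate y_jt with μ̂_t as an *offset* (coefficient fixed at 1),

    y_jt = μ̂_t + x_jt' a + b_j + ε_jt,    b_j ~ N(0, σ_b²),  ε_jt ~ N(0, σ_ε²),

fitted by profiled REML/ML, with Wald t/p values, BLUPs of the practice
effects b_j and their prediction intervals.

**Diagnostics.**  Residual autocorrelation functions; empirical variograms of
the practice effects, v_ij = ½(y_i − y_j)², with permutation envelopes (99
permutations of trend-surface-detrended values over the locations); and the
spatiotemporal variogram over 1-km distance bins (up to 20 km) × time lags
0–3 months.  Observed variograms inside the envelope and a structureless
spatiotemporal surface indicate the model left no residual spatial or
spatiotemporal correlation.

A synthetic-panel generator (`gen_panel`) emulates the study design this
toolkit targets — 63 practices × 55 months in a 20 km window — with drifting
seasonality, a shared temperature driver, practice covariates, random
intercepts, and iid / spatial / spatiotemporal residual options, always
returning the ground truth alongside the panel.

The models are scikit-learn style estimators (`DynamicHarmonicRegression`,
`StaticHarmonicRegression`, `RandomInterceptModel`) with `fit`, `predict`,
`get_params` and trailing-underscore fitted attributes.

## Worked example

```python
from dhrpanel import PanelGenConfig, RunConfig, run_pipeline

cfg = RunConfig(seed=1, simulate=PanelGenConfig(seed=1, temp_lag_days=7))
summary = run_pipeline(cfg, "run")

s1, s2, dg = summary["stage1"], summary["stage2"], summary["diagnostics"]
print(f"selected temperature lag : {s1['selected_lag']}")
print(f"dynamic R^2 at best lag  : {s1['r2_dynamic_best']:.3f}")
print(f"static  R^2 at best lag  : {s1['r2_table'][s1['selected_lag']]['static']:.3f}")
print(f"sigma_b^2 (practices)    : {s2['sigma_b2']:.5f}")
print(f"sigma_e^2 (residual)     : {s2['sigma_e2']:.5f}")
print(f"BLUP variogram inside envelope: {dg['envelope_bins_inside']}/{dg['envelope_bins']} bins")
```

prints

```
selected temperature lag : 7d
dynamic R^2 at best lag  : 0.998
static  R^2 at best lag  : 0.979
sigma_b^2 (practices)    : 0.01032
sigma_e^2 (residual)     : 0.00272
BLUP variogram inside envelope: 20/20 bins
```

The panel was generated with a 7-day-lagged temperature effect, and lag
selection recovers it; the dynamic fit beats its static counterpart because
the simulated seasonal amplitudes drift between years; the variance-component
estimates sit close to the generating values (σ_b² = 0.01, σ_ε² = 0.0025); and
because the generated residuals are iid, the practice-effect variogram lies
entirely inside its permutation envelope — the diagnostic signature of "no
remaining spatial correlation".  `run/` now contains the panel, the stage-1
offset table, the fixed-effects table, BLUPs with intervals, the envelope and
spatiotemporal-variogram tables, and `summary.json`.

The same stages are available from the shell:

```sh
dhrpanel simulate --seed 1 --out data/
dhrpanel fit-dhr  --panel data/panel.csv --locations data/locations.csv \
                  --temperature data/daily_temperature.csv --out stage1/
dhrpanel fit-mixed --panel data/panel.csv --locations data/locations.csv \
                   --offset stage1/offset.csv --out stage2/
dhrpanel diagnose --residuals stage2/residuals.csv --what envelope --out env.csv
dhrpanel run --config config.yaml --out run/
```

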