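# Methods

This note records the modelling choices in `sawdens`: what is assumed,
what is configurable, what the synthetic generator does and does not
emulate, and where the numerics could bite.

## Catch model

Juvenile catch per gillnet set is Tweedie-distributed with mean
`mu = E * exp(eta)` and variance `phi * mu^p`, `1 < p < 2`.  The offset
`log E` uses effort in yard-minutes (soak minutes x net area in square
yards, 1 m = 1.09361 yd).  The linear predictor combines penalized
B-spline smooths of continuous covariates with parametric factor terms.

Implementation details:

- **Basis.** Cubic B-splines, basis dimension `k = 10` per smooth
  (fitted effective degrees of freedom land well below that on
  realistic data, so the basis is not the binding constraint).  Each
  smooth carries a sum-to-zero (centering) constraint so the basis is
  orthogonal to the intercept.  Interior knots sit at data quantiles
  and are forced to be distinct: zero-inflated covariates such as the
  mangrove focal sum would otherwise stack coincident knots and
  degenerate basis columns (quantiles fall back to unique values, then
  to equal spacing).
- **Smoothing selection.** Penalized IRLS (statsmodels `GLMGam`) with
  per-smooth penalty weights chosen by coordinate-wise grid search
  (grid `10^-2 .. 10^6`, two passes) minimizing a conditional AIC:
  `-2 * loglik + 2 * (edf + 2)`, where the log-likelihood is the
  Tweedie series density evaluated at the fitted means with the Pearson
  dispersion estimate, `edf` is the trace-based effective degrees of
  freedom, and the `+2` counts dispersion and power.  Fits whose edf
  falls outside sane bounds (per-coefficient edf outside [-0.5, 1.5])
  are rejected as numerically degenerate.  The AIC definition is
  recorded verbatim in every serialized fit.
- **Power selection.** The Tweedie power is profiled over the grid
  1.05, 1.15, ..., 1.95 against the same criterion, then re-profiled
  once after smoothing selection.  A fixed power can be supplied
  (`fit(power=1.5)`), which the replicate experiments use.
- **Cross-check.** One test fits the same single-smooth Tweedie model
  in mgcv (REML, P-splines) through `Rscript` and requires the two mean
  surfaces to agree (log-scale correlation > 0.98); mgcv is used only
  as an independent oracle, never as the estimator.
- **Deviance explained** is `100 * (1 - D_model / D_null)` with the
  null model an intercept + offset GLM of the same family and power.
- **Prediction** clips covariates to the fitted range and flags such
  rows as extrapolated; standard errors come from the delta method on
  the penalized coefficient covariance.

## Model selection

All subsets of the toggleable candidate covariates are enumerated
(2^k; the default candidate set of ten toggleable terms gives 1024),
`year` and `developed_sl` are always included (`always_include` is
configuration), and any spec containing a covariate pair with Pearson
|rho| > 0.7 on the fitting table is discarded.  Among converged fits,
those within 2 AIC points of the minimum are competitive; the winner
has the highest mean cross-validated AUC, with ties broken by fewer
covariates, then lower AIC.  Complete-case analysis is used throughout
(covariates with missing habitat values drop rows for specs that use
them), so nested specs can see slightly different n — as happens with
real survey tables.

## Validation

Cross-validation stratifies folds on presence/absence so folds retain
positives where possible, holds the selected smoothing weights and
power fixed, and reports per-fold RMSE on the count scale and AUC from
the full ranking of held-out predictions; the training-fold median
prediction also defines an operating threshold whose sensitivity and
specificity are reported.  Folds without positives skip AUC with a
warning.

The external statistic divides the prediction at each sighting by the
same-day median prediction over all valid-depth (0–3 m) cells and
subtracts one.  The construction is scale-free, so catchability and
units cancel.  An alternative per-day Z-scoring of log predictions is
available (`zscore_mode="zlog"`) as a sensitivity check, because the
ratio reading of the statistic is a design choice.

## Abundance

The prediction grid clips microgrids to within 61 m of the shoreline
and keeps cells no deeper than 3 m (boundary inclusive); soak area is
the clipped polygon area converted to square yards, so totals are
relative abundance on the survey's effort scale with catchability
treated as 1 (as estimated for this gear in the study system; no
catchability variance is propagated).  Coefficient uncertainty enters
through posterior draws — a Metropolis–Hastings chain on the penalized
likelihood (independence multivariate-t proposals centred at the
estimate alternating with random-walk steps; burn-in 200, thinning 2)
or a Gaussian approximation `N(beta_hat, V_hat)`.  Season-level
environmental input is the per-cell mean of daily fields sampled every
7 days within the season — the fields are smooth in time, and weekly
sampling changes seasonal means negligibly while keeping the run cheap.
Draws whose total exceeds `trim_factor` (default 100) times the
cross-draw median are trimmed before summaries; the factor is recorded
in output metadata and `trim_factor = inf` disables trimming exactly.
Year effects are compared by one-way ANOVA on draw-level totals with
Tukey HSD and a greedy compact-letter display (draw-level totals rather
than cell-level densities; the alternative is noted as a design
option).  Interannual change is the series of year-over-year ratios of
yearly medians.

## Demography

Juvenile-female abundance is a truncated normal (mu = 251.481,
sigma = 81.41511, a = 178.511, b = 504.7369); with a 50:50 sex ratio
total juveniles are twice the female draws, which reproduces the
rounded summaries 503 (median), 357 (minimum) and 1009 (maximum).

- **Brood-size route.**  In summary mode: median / brood midpoint
  (10.5) and range endpoints min/brood_max, max/brood_min, each rounded
  half away from zero — 48 with range 26–144.  A Monte-Carlo mode
  divides truncated-normal juvenile draws by Uniform(7, 14) brood sizes
  (continuous by default, integer by flag) and reports median, SD and
  range; its SD (~16–17) is reported alongside the summary-mode point.
  The biennial reproductive cycle is treated as embodied in dividing
  the two-cohort standing abundance by a single brood; no extra factor.
- **Stable-age route.**  Per realization, juvenile females F and an
  integer maturity age m ~ Uniform{7..11} give adults
  `F * sum(ratio[age >= m]) / (ratio0 + ratio1)`.  The species'
  published stable-age vector is not printed in any source shipped
  here, so the package provides a clearly labelled *synthetic*
  geometric life-table vector (flat survival 0.8 to age 30) for
  demonstration; results using it are order-of-magnitude only, and the
  route's exact published output is not reproducible without the true
  vector.

## Synthetic estuary

The generator supplies the statistical structure the analysis assumes,
not cartography: a rectangular estuary open to the sea at its southern
edge with three straight rivers (one carrying a developed-shoreline
stretch), depth shoaling toward shore, mangroves concentrated along
shorelines and near river mouths at sub-cell (25 m) resolution, and
daily temperature / dissolved-oxygen / salinity / pH fields built from
seasonal sinusoids, an upriver salinity gradient, and spatially
correlated noise, clipped to the observed environmental envelopes of
the study system (temperature 14.7–35.8 degC, DO 0.4–11.9 mg/L,
salinity 0.1–35.9).  Every field for a given day is regenerated
deterministically from (seed, day ordinal), so nothing is stored.

Surveys follow the monitoring design: stratified random draws of
shallow (<= 3 m) microgrid cells per river region per month, 16 sets a
month over 2010–2022 (~2500 sets), 61 m x 2.5 m nets soaked 60 minutes
(net height is not part of the field protocol record, so it is
configuration, default 2.5 m).  Catches are exact compound
Poisson–gamma draws with mean `effort * exp(eta_true)`; the default
intercept (-14.3) calibrates the total catch index to the order of one
hundred juveniles over the series — the sparse regime of the real
programme.  The embedded Poisson count is the integer number of
individuals and carries simulated lengths (a two-component age-0/age-1
mixture) and sexes, so the continuous Tweedie response used for model
fitting and the per-fish records stay mutually consistent.  Sightings
are drawn cell-wise proportional to the true density on random dates
(or uniformly, or with explicit weights, for controls).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: tidal and sub-daily
dynamics, prey/predator fields, benthic substrate, observation effects
beyond the effort offset (net avoidance, saturation), spatial
autocorrelation in catches beyond what the shared environmental fields
induce, and real estuary geometry.  Recovery results certify the
statistical machinery under the stated generating process, not the
ecological conclusions for any particular estuary.

## Ground-truth experiment sizes

The replicate experiments are sized to certify the machinery in
minutes on one core: 20 replicate surveys of ~2500 sets for
smooth-effect recovery and selection consistency (each active smooth
scaled to a realized log-scale effect SD of ~0.45, catch rate ~0.1 per
set so shapes are estimable); 500 sightings per validation control; a
compact 24 x 20-cell, 6-year estuary with 400 Gaussian posterior draws
per replicate for interval coverage.  Selection replicates compare
subsets at the smoothing weights selected for the full model (a
standard device that keeps the AIC comparison fast and fair).

## Known limitations

- The smoothing criterion is AIC-flavoured rather than true REML;
  edf-based AIC with the Pearson scale mildly under-smooths relative
  to mgcv's REML in our mgcv comparison, without changing the fitted
  mean surface materially.
- The MH sampler is a short, fixed-length chain tuned for moderate
  dimension (~30 coefficients); no convergence diagnostics are
  computed.  The Gaussian sampler is exact for the quadratic
  approximation and is used wherever speed matters.
- Ordinary kriging uses a fixed exponential variogram (range 2000 m)
  rather than fitting the variogram per day; days with under 3
  observations fall back to the season-mean field.
- The compact letter display is greedy (groups processed in mean
  order), which can occasionally produce a non-minimal letter set;
  pairwise decisions themselves come from Tukey HSD.
- `interpolate_environment` and the raster toolchain assume a
  projected, metre-based coordinate system throughout.
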