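# sawdens

Spatiotemporal density modelling, relative-abundance trend estimation,
and breeding-female back-calculation for juvenile smalltooth sawfish
(*Pristis pectinata*) from random gillnet surveys — with a synthetic
estuary generator that provides known ground truth for every stage.

## Who this is for

Quantitative ecologists and protected-species analysts working with
fishery-independent monitoring of rare, patchily distributed estuarine
species: encounter rates of a few captures per hundred gillnet sets,
strong habitat structure (mangrove shorelines, shallow brackish water),
and a need for defensible abundance trends and uncertainty statements.

## The model

Catch per gillnet set is modelled as a Tweedie generalized additive
model with a log effort offset:

    n_i ~ Tweedie(mu_i, p, phi),  1 < p < 2
    log mu_i = log(E_i) + beta_0 + sum_j s_j(x_ij) + gamma' z_i

where `E_i` is soak effort in **yard-minutes** (soak minutes x net area
in square yards), the `s_j` are penalized B-spline smooths of
environmental and habitat covariates (dissolved oxygen, temperature,
salinity, mangrove focal sums, year, distance to river mouth, ...), and
`z_i` holds parametric factors (season, river, developed-shoreline
flag).  For `1 < p < 2` the Tweedie is a compound Poisson–gamma with an
atom at zero — the right shape for zero-inflated, overdispersed catches.

Around the model sit the pieces of a complete survey-analysis workflow:

- **Habitat rasters** — supervised maximum-likelihood classification of
  multiband shoreline imagery with per-pixel class priors (mangrove
  prior reduced to 2% in urban pixels), Euclidean distance from
  mangrove cells to the shoreline within a 10 m buffer, 8x8 focal sums
  of mangrove presence (values 1–64), and zonal statistics onto 200-m
  sampling microgrids.
- **All-subsets selection** — every combination of toggleable
  covariates (2^10 = 1024 with the default ten), a Pearson |rho| > 0.7
  collinearity filter, AIC short-listing (within 2 points), and a
  cross-validated AUC tie-break.
- **Validation** — stratified ten-fold cross-validation (RMSE, AUC with
  a training-median operating threshold) and an external consistency
  score: model predictions at independent sighting locations divided by
  the domain-wide daily median prediction over valid depths (0–3 m),
  minus one; the proportion of scores above zero and a one-sample
  t-test quantify agreement.
- **Abundance** — microgrids clipped to within 61 m of shore and depths
  of at most 3 m form the prediction grid; 1000 posterior coefficient
  draws (Metropolis–Hastings over the penalized likelihood, or a
  Gaussian approximation) propagate uncertainty into yearly, seasonal
  abundance totals; extreme draws are trimmed; ANOVA + Tukey HSD with a
  compact letter display test interannual differences.
- **Demography** — adult females back-calculated from juvenile
  abundance by the brood-size route (divide by 7–14 pups per brood,
  biennial cycle) and the stable-age route (female half of the
  juveniles scaled by stable-age ratios, maturity uniform on ages
  7–11).
- **Synthetic world** — a schematic three-river estuary with bathymetry,
  mangrove rasters, daily environmental fields, stratified random
  gillnet surveys, and sightings, all generated from a known density
  surface so that every statistic above can be tested against truth.

## Worked example

```python
from sawdens import (DensityGAM, EnvFieldSeries, ModelSpec, TrueModel,
                     generate_scene, simulate_survey)
from sawdens.demography import DemographyConfig, broodsize_backcalc

scene = generate_scene(seed=1)
env = EnvFieldSeries(scene, seed=1)
survey = simulate_survey(scene, env, TrueModel(), seed=1)
print(f"sets: {len(survey)}, total catch index: {survey.n_caught.sum():.1f}")

spec = ModelSpec(smooths=("avg_do", "avg_temp", "sum_mnn", "year"),
                 factors=("developed_sl",))
result = DensityGAM(survey, spec).fit()
print(result.summary())

brood = broodsize_backcalc(DemographyConfig(), seed=1)
print(f"adult females: {brood.point:.0f} +/- {brood.sd:.0f} "
      f"(range {brood.low:.0f}-{brood.high:.0f})")
```

prints

```
sets: 2496, total catch index: 97.6
Tweedie density GAM
================================================================
formula: n_caught ~ s(avg_do) + s(avg_temp) + s(sum_mnn) + s(year) + developed_sl + offset(log effort_yard_min)
family: Tweedie(p=1.45)  scale=3.8610
n=2496  dropped (incomplete)=0

Parametric coefficients:
term                      estimate        SE        t        p
Intercept                 -12.7014    0.1068 -118.913   0.0000
developed_sl[1]            -0.4902    0.4236   -1.157   0.2473

Smooth terms (edf):
  s(avg_do        ) edf =  3.731
  s(avg_temp      ) edf =  3.368
  s(sum_mnn       ) edf =  3.237
  s(year          ) edf =  6.441

AIC = 1480.01   deviance explained = 7.1%
total edf = 18.77   converged = True
adult females: 48 +/- 17 (range 26-144)
```

The simulated survey reproduces the sparse regime of the monitoring
programme (~2500 sets, a catch index near 100); the fitted intercept is
the log catch rate per yard-minute; the smooth edf values show how much
flexibility each habitat effect earned; and the demographic
back-calculation turns a juvenile abundance distribution into a count
of breeding females.

A command-line interface wraps the stages
(`sawdens synth | rasters | prep | fit | validate | abundance |
demography | run`); `sawdens run --out DIR --seed N` executes the full
pipeline and writes every stage artifact (CSV/GeoJSON/TIFF/JSON/YAML)
into the run directory.

## Layout

- `src/sawdens/scene.py`, `environment.py`, `surveysim.py`, `tweedie.py` — synthetic estuary, environmental fields, surveys, sightings
- `src/sawdens/rasters.py` — classification, distances, focal sums, zonal statistics
- `src/sawdens/survey.py` — effort, seasons, age classes, CPUE, kriging
- `src/sawdens/model.py` — `DensityGAM` / `DensityGAMResults`
- `src/sawdens/selection.py`, `validate.py` — all-subsets AIC/AUC selection, cross/external validation
- `src/sawdens/abundance.py`, `demography.py` — posterior abundance, trend tests, back-calculation
- `src/sawdens/pipeline.py`, `cli.py`, `io.py` — orchestration and interchange formats
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
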