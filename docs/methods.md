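# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, what the synthetic-data generator does and
does not emulate, and the numerical conventions a user should know before
trusting (or extending) the outputs.

## Scope and data model

The unit of analysis is the *catchment*: one row of predictors
(anthropogenic: Olsen P, population density, six land-class percentages;
biophysical: biome, continent, latitude, slope, runoff, potential
evapotranspiration, area, population) linked to a monitoring *site* with a
daily discharge series and dated nutrient samples for up to four analytes
(DRP, TP, NO3-N, TN; concentrations in mg/L throughout, except the
chlorophyll equation which takes µg/L). Spatial structure is deliberately
abstract — a catchment's area and population are scalar attributes, and no
polygon or raster handling is attempted.

## Sample preparation

Periphyton accrues under stable baseflow, so samples influenced by storm
runoff are removed before medians are taken.

- **Baseflow separation.** Lyne–Hollick single-parameter recursive filter,
  written in its baseflow form
  `b_t = min(q_t, α·b_{t−1} + (1−α)/2·(q_t + q_{t−1}))` with `b_0 = q_0`,
  applied in 3 direction-alternating passes with α = 0.925. The filter
  family is standard in hydrology; α and the pass count are exposed in the
  config because the literature uses values from 0.9 to 0.98 and 1 to 9
  passes. The clamped form guarantees 0 ≤ baseflow ≤ flow at every step
  and makes the filter idempotent on constant (pure baseflow) series.
- **Stormflow exclusion.** A sample survives when same-day stormflow
  (flow − baseflow) is strictly below 25% of that day's flow; "≥ 25%"
  excludes. Zero-flow days carry no stormflow and are retained. Samples
  whose date is missing from the discharge record cannot be attributed and
  are dropped with a logged count.
- **Growth season.** |latitude| < 23.5° (the Tropic lines) counts as
  tropical and uses all months; otherwise May–October in the Northern
  Hemisphere, November–April in the Southern.
- **Site medians.** Median of surviving growth-season samples, with the
  mean-of-middle-two convention for even counts; the observation count
  `n_obs` is kept as the model sample weight. Sites with no surviving
  samples are excluded downstream rather than imputed.

## The human-effect composite

Eight variables are transformed onto comparable scales, oriented so each
increases with anthropogenic pressure:

| component | transform |
|---|---|
| Crop, Pasture, Urban | `asin(√(p/100))` |
| Forest, Rangeland, Lentic | `asin(√((100−p)/100))` |
| Olsen P | `ln(1.8578 · olsen_p)` |
| Population density | `ln(0.0282 · pop_density)` |

Logs are natural; the two multiplicative constants place the transformed
spreads of Olsen P and population density within those of the
arcsine-transformed land classes. Population density is floored at 1e−6
persons/km² before the log so that pristine catchments (the reference value
0.001 is representable) never produce −∞.

Per analyte the composite is a weighted sum of the eight components. Two
weight sources are supported: the published per-analyte coefficient sets
(the default for reproduction work) and a fitted path — the first partial
least squares (PLS) component of the transformed matrix against ln(median
concentration), computed with scikit-learn's `PLSRegression`
(`n_components=1`, unscaled by default), unit-norm, sign-oriented so the
latent score correlates positively with the response. For a single
response the first PLS weight vector is analytically the normalised
cross-covariance `X'y/‖X'y‖`; the test suite asserts equality with that
closed form to 1e−10. The Bayesian shrinkage prior that originally
produced the published coefficients is not reconstructed; the printed
coefficients are taken as given.

## Concentration models

`ln(median)` per site is modelled with random-forest regression
(`RandomForestRegressor`), with `n_obs` as the sample weight both in tree
fitting and in every MAE/RMSE computed here.

- **Split.** 75/25 train/test, stratified on quantile bins of the response
  so the two distributions match.
- **Tuning.** Exhaustive grid search by weighted 10-fold CV MAE. The grid
  covers tree counts (≤ 900; adding trees beyond this yields little),
  features per split, and minimum leaf size. *A caution that shaped the
  defaults:* the reference-condition counterfactual evaluates the forest
  at the extreme low end of the human-effect distribution, where forests
  with large leaves or heavy feature subsampling regress predictions
  toward the bulk of the data and can attenuate recovered enrichment to a
  small fraction of its true value (measured on synthetic data with known
  truth). The default grid therefore includes the deep/full-feature corner
  (`min_samples_leaf` ∈ {1, 5}, `max_features` ∈ {√P, P}); CV-MAE tuning
  selects it whenever the signal-to-noise ratio supports it.
- **Backward elimination.** From the full predictor list, each iteration
  tunes, fits, and drops the lowest impurity-importance predictor, never
  dropping latitude, human effect, or biome (the counterfactual must be
  expressible through them). Biome enters one-hot and its dummy
  importances are summed before ranking. P predictors with F fixed yield
  P − F + 1 candidates (25 → 23 with the standard trio).
- **Selection.** Smallest test-set MAE; candidates within 1% (relative)
  of the best are treated as ties and resolved toward fewer predictors,
  then toward the earlier (larger-model) candidate. Test MAE rather than
  CV MAE drives selection.
- **Metrics.** MAE and RMSE on the ln scale (weighted); R² is the squared
  correlation from a regression of observations on predictions, with
  constant predictions scoring 0 by convention.
- **Uncertainty.** Sites are resampled with replacement (default 1000
  reps), the selected architecture refit each time, and percentile 95%
  intervals taken per prediction target. Current-condition and
  reference-condition intervals come from the same resamples. The interval
  is widened if needed to contain the full-data point prediction.
- Prediction with a biome level unseen in training raises a named error
  (`UnknownBiomeError`) rather than guessing.

## Reference conditions, enrichment, validation

- **Reference inputs:** Olsen P = 2 mg/kg, population density = 0.001
  persons/km², crop = pasture = urban = 0, with the displaced percentage
  split half to forest and half to rangeland; lentic share and all
  biophysical fields are untouched. Only the human-effect feature changes
  at prediction time, recomputed from the pristine inputs.
- **Enrichment:** `100·(current − reference)/reference`, computed on the
  mg/L scale after back-transforming predictions. The 95% bounds follow
  the asymmetric rule for a ratio of uncertain quantities: lower =
  `100·(cur_lo − ref_hi)/ref_median`, upper = `100·(cur_hi −
  ref_lo)/ref_median`. The pair is always ordered but need not bracket the
  point estimate; this is a property of the rule, not a bug.
- **MDC validation:** catchments with Olsen P ≤ 5 mg/kg (a stricter
  ≤ 2 variant is configurable), population ≤ 0.001/km², forest+rangeland
  ≥ 80%, and no crop or urban land serve as an empirical check: per biome,
  the mean observed MDC median should fall inside the biome-mean reference
  interval. Biomes with ≤ 5 MDC sites are flagged low-confidence.
- **Summaries:** area-weighted means of enrichment and of its CI bounds by
  biome, continent, or world, after removing catchments flagged excluded
  (desert/xeric and taiga biomes, permafrost-origin). The fraction of
  catchments whose reference value lies inside the current-condition
  interval is reported alongside (a gauge of how many catchments have
  little manageable headroom). Weighted aggregation of percentile bounds
  is approximate — the bounds are averaged with the same area weights as
  the point estimates — because the joint distribution across catchments
  is not retained in the summary tables.

## Periphyton biomass and classes

`log10(max chl) = 0.349·log10(TN) + 0.256·log10(TP) + 0.722` with TN and
TP in µg/L and chlorophyll in mg/m². The µg/L + base-10 convention is the
only one that reproduces the conventional ≈ 150 mg chl-a/m² boundary at
TN = 0.800 and TP = 0.046 mg/L (it evaluates to 144.8); it is fixed in the
module constants and noted here because the source equation is printed
without units.

Classes 1–6 cross the TN:TP **mass** ratio bands (< 7 N-limited, 7 ≤ r <
15 co-limited, ≥ 15 P-limited) with the thresholds. Two conventions make
the rules a partition: class 4 uses TP ≥ 0.046 (the printed > would leave
a boundary gap), and class 4 is labelled *undesirable* (its rule requires
both nutrients elevated; the alternative label would make classes 3 and 4
indistinguishable). Shares per class are aggregated by land area and by
population, per continent and for the world, excluded catchments removed;
within each scenario the six shares sum to 100%.

## The synthetic world

The generator exists so that every stage has an oracle. It emulates:

- right-skewed Olsen P and population density (log-normal), compositional
  land shares (Dirichlet), biomes with plausible latitude bands, and a
  configurable fraction (default 0.1) of minimally disturbed catchments so
  reference predictions have low-pressure support;
- daily discharge as a seasonal sinusoid plus Poisson-arriving storm
  pulses with a 3-day exponential decay, storm volume set by the baseflow
  index (default 0.7, ~12 events/yr);
- concentrations `C = ref(biome) · exp(slope·H + ε)`, ε ~ N(0, sd), where
  H is the human-effect score of the catchment's own inputs under the
  published weights. Defaults: slope 0.08 — chosen once so that typical
  developed catchments sit a few tens of percent above reference, the
  order of magnitude reported for real rivers — and log-noise sd 0.1.
  Biome reference levels default to realistic baseflow values (e.g. TN
  0.15–0.6 mg/L, TP 0.015–0.06 mg/L), graded from oligotrophic montane
  systems to naturally richer grasslands.

It does **not** emulate: spatial autocorrelation between catchments,
censored/detection-limit values, laboratory method changes, flow-dependent
concentration within a site (concentration is independent of the
hydrograph, so the stormflow filter is exercised structurally, not
causally), or analyte covariance beyond the shared human-effect signal.
Passing tests therefore demonstrate the machinery is correct under the
stated data-generating process, not that real-world enrichment estimates
carry these error rates.

## Problem sizes and numerical conventions

- The default pipeline simulates 200 catchments × 3 years of daily flow,
  with 2 samples/month per analyte; tests and worked examples use 50–500
  catchments and 20–200 bootstrap reps, sizes chosen so the whole suite
  runs on a laptop-class single CPU in a few minutes.
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawns (catchment index, stage, analyte), so
  a re-run with the same config is byte-identical, including CSV output.
- Ties in grid search and model selection break toward the earlier grid
  cell / larger candidate deterministically.
- Degenerate inputs have defined behaviour: empty or gapped discharge and
  non-positive concentrations are schema errors with row indices; a site
  with no surviving samples is excluded; an all-excluded summary group
  returns an empty table with a warning; `reps < 2`, `alpha ∉ (0,1)`, and
  even pass counts are rejected.

## Known limitations

- Random-forest counterfactuals cannot extrapolate outside the support of
  the training data; reference predictions are only trustworthy when some
  low-pressure (MDC-like) sites exist per biome. The MDC validation report
  is the intended guard — treat biomes that fail it, or that carry the
  low-confidence flag, as unreliable.
- Residual attenuation of a few percentage points in recovered enrichment
  remains even with deep forests, most visible in biomes with few
  catchments; the bootstrap intervals usually, but not always, absorb it.
- The asymmetric enrichment CI is conservative by construction and widens
  quickly when reference uncertainty is large.
- The fitted-PLS path estimates weights per analyte independently; no
  shrinkage toward a common mean is applied, so with few sites the fitted
  weights are noisier than the published sets.
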