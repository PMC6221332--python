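# Methods

## Exposure metrics

`heatthresh.weather` derives 19 candidate exposure metrics per station-day
from raw daily records (tmin/tavg/tmax in °C, relative humidity %,
precipitation mm, wind m/s, two solar-radiation summaries) and optional
hourly temperatures.

* **Trailing means.** `AvgTmaxLagK` is the mean of Tmax over days
  i−K..i (K = 1..3); likewise for the daytime mean `Tavg1218`. The first K
  days of each contiguous station series are missing. The "two consecutive
  day" exposure of operational warning rules corresponds to `AvgTmaxLag1`.
* **Daytime window.** `Tavg1218` averages the six hourly observations
  stamped 12:00–17:00 — the half-open interval [noon, 6 PM) with stamps
  marking hour starts. Any missing hour in the window yields a missing
  value (counted and logged, never imputed).
* **Gap variables.** `TmaxGap`/`TavgGap` are the signed day-to-day
  differences, exactly as defined. (The source study's summary table
  reports implausibly non-negative statistics for these; the signed
  definition is implemented as printed and the discrepancy left alone.)
* **Heat index (Nindex1).** The Rothfusz nine-term regression in °F on
  (T, RH), with the NWS low-humidity subtraction
  ((13−RH)/4)·√((17−|T−95|)/17) for RH < 13 and 80 ≤ T ≤ 112 and
  high-humidity addition ((RH−85)/10)·((87−T)/2) for RH > 85 and
  80 ≤ T ≤ 87. The sign of the T²·RH coefficient is +0.00122874: the
  standard NWS value, and the only sign under which the index is a
  temperature-like quantity. The NWS simple-formula fallback below 80 °F
  exists behind `use_simple_below_80` but is off by default — the full
  regression is the defining formula here. Daily-mean temperature
  (converted °C→°F) and daily-mean humidity are the inputs.
* **Discomfort index (Nindex2).** Thom's formula
  1.8·Tc − (1 − 0.01·RH)(Tc − 14.3) + 32 on the same inputs in °C.
* **Missing-data policy.** Missing inputs propagate to missing features;
  rows with a missing model covariate are dropped at fit time with a
  logged count.

## Spline engine

`heatthresh.mars` implements hinge-basis adaptive spline regression
(MARS) with a statsmodels-style surface (`MarsRegression.fit()` →
`MarsResults`).

* **Forward pass.** Starting from the intercept, each step adds the
  reflected pair parent × {(x−t)₊, (t−x)₊} that maximises the RSS decrease,
  with all coefficients refit by OLS. Candidate knots are the observed
  covariate values with `min_span` (default 5) observations trimmed at
  each end. The search is exact but fast: the downward member is an affine
  function of the upward one ((t−x)₊ = (x−t)₊ − x + t), so only upward
  hinge columns are materialised, and the orthonormal design basis only
  gains columns between steps, so cached projections stay valid. The pass
  stops at `max_terms` basis functions (default 21, counting the
  intercept), when the relative RSS improvement drops below 1e−5, or when
  the GCV denominator would saturate.
* **Knot spacing.** Knots on the same variable must sit at least
  `min_knot_gap` candidate-grid positions apart (default: the standard
  adaptive span ≈ −log₂(−log(0.95)/(p·n))/2.5, about 7 at n = 5000).
  Without this, pairs of near-coincident knots with huge cancelling
  coefficients chase individual noisy observations.
* **Degree-2 terms.** Optional (`max_degree = 2`); the composite indices
  (Nindex1, Nindex2) are barred from interactions by default since they
  already combine temperature and humidity. A reflected pair always enters
  together; either member may be pruned alone.
* **GCV and backward pass.** GCV = (RSS/n)/(1 − C/n)² with
  C = 1 + n_terms + d·n_knots, d = 3 when interactions are allowed, else
  2; n_knots counts distinct (variable, knot) pairs, so a surviving
  reflected pair is one knot. Pruning deletes the term whose removal least
  increases the refit RSS and returns the visited subset with minimum GCV;
  for models of ≤ `exhaustive_prune_limit` (default 10) terms every subset
  is visited, making the selection exact — pure greedy deletion provably
  misses the optimum in simple cases, because the near-zero twin of a
  reflected pair is always the cheapest deletion and strands the
  pair-only subset off the path.
* **Importance.** Along the greedy pruning path, the GCV increase caused
  by deleting a term is credited to each variable in it; scores are summed
  per variable, ties break by forward-pass RSS reduction then name, and
  only variables retained in the final model are ranked. With strongly
  correlated exposures (the heat index and the two-day mean maximum
  correlate at ~0.86 in the simulator) the top two ranks can be close —
  whichever variable survives longest in the path collects the shared
  signal's credit.
* **Tie-breaking.** Deterministic: ties in RSS decrease resolve toward the
  smaller variable index, then the smaller knot. `FitConfig.seed` is
  reserved for optional stochastic tie-shuffling and unused by default.
* **Degenerate inputs.** Constant response → intercept-only model;
  rank-deficient candidate pairs fall back to the independent member or
  are skipped; fitting requires ≥ 10 complete observations.

## Threshold extraction

A fitted model defines a heatwave threshold per variable as the knot where
its additive component turns upward most sharply. The slope increase at a
knot equals the sum of the coefficients of the hinges sharing it (upward
`c(x−t)₊` contributes +c at t; downward `c(t−x)₊` has slope −c below t, so
it also contributes +c at t). Each candidate knot is scored by
min(slope increase, outgoing slope) and the best positive score wins;
knots failing the test, and all interaction terms, become annotations.
This reduces to reading the upward hinge's knot in cleanly printed models,
but remains correct when a fit encodes one bend as several partially
cancelling hinges or prepends a falling-to-flat segment — both routine
outcomes of greedy hinge selection under correlated covariates.

## Warning criteria and calendars

Criteria come in three kinds: `consecutive_exceed` (variable strictly
exceeds the cutoff on `run_length` consecutive days ending today — the
operational phrasing "exceeds 33 °C for two consecutive days"; a 3-day run
therefore contributes 2 flagged days), `level_exceed` (≥ cutoff, matching
the "≥ 32.58" phrasing of the derived alternatives), and `disjunction`
(OR of members). The strict-vs-inclusive distinction is deliberate and
tested at exact-cutoff inputs. Days with missing inputs (including
run-length warm-up days) are unflagged and tallied in a missing report.
Yearly counts are reported against the eligible-day denominator — 92
June–August days per year, 552 over 2011–2016. Presets `kma_existing`
(Tmax > 33, run 2), `alt1_avgtmaxlag1` (≥ 32.58), `alt2_nindex1`
(≥ 79.64) and `alt3_or` carry the published comparison cutoffs; note these
differ slightly from the fitted knots (32.95/79.65) — both pairs are kept
as given, uncorrected.

## Synthetic data

The generator emulates the study conditions, not any particular year of
real weather.

* **Weather.** Daily mean temperature = cosine annual cycle (peak 27 °C
  around Aug 1, amplitude 20 °C) + AR(1) anomalies (φ = 0.7, innovation sd
  1.8 °C); tmax/tmin sit ± half the 8.5 °C diurnal range with bounded
  jitter that preserves ordering; hourly temperatures follow a cosine
  through (tmin, tmax) peaking at 15:00. Relative humidity (mean 75, sd
  13) anticorrelates (ρ = −0.6) with the total temperature deviation — hot
  spells are the dry, sunny ones; precipitation is Bernoulli–gamma; solar
  input shrinks on wet days. The parameters are set so the summer
  covariates straddle the published knots (at default settings ~16% of
  high-summer days exceed AvgTmaxLag1 = 32.95), which is what makes knot
  recovery identifiable. What the generator does not emulate: spatial
  correlation between stations, monsoon timing, multi-day rain persistence
  and real extreme-event tails — so passing recovery tests demonstrate
  correctness of the estimation machinery under the modelled conditions,
  not robustness to every real-weather feature.
* **Morbidity.** y = model prediction + Normal(0, noise_sd), optionally
  floored at 0. Gaussian additive noise on the standardized rate matches
  the least-squares estimation; it is not a count model (a Poisson variant
  on panel counts exists through the study emulator's count rounding, but
  the default target of inference is the continuous rate).
* **Study panel.** n_centers × n_days rows (74 × 521 = 38,554 at full
  scale). County populations draw from the published moments (mean
  303,011, sd 143,257, floored); total counts are the standardized rate
  quantised to counts (count = rint(y·pop/scale), scale 100,000 by
  default, so the stored rate is count/pop·scale); subgroup counts are
  multinomial within each subcategory (ages ~6/69/25%, ~79% male,
  ~36/64% discharged/admitted, ~24/76% indoor/outdoor) and therefore add
  up exactly, while the June–July vs August split follows the row's
  calendar date. The study window helper produces June 1–Aug 31 per year
  (92 days) by default and accepts the per-year surveillance windows as
  overrides.
* All generators are pure functions of (config, seed); identical seeds
  give byte-identical output.

### A note on the published summary envelope

The published variable-summary table is internally inconsistent for the
composite indices: the row labelled as the heat index (max 85.1) equals
the discomfort-index formula at the mean inputs, while the row labelled as
the discomfort index (range 56.86–107.88) matches the heat index — no
heat-index variant can stay below 85.1 when the daily mean reaches
32.9 °C. The generator therefore targets the physically consistent
(swapped) envelope; the realism check logs the Tmax/Whum/Nindex1 coverage
fractions and asserts only the uncontested ones.

## Validation experiment

The central check refits the engine to synthetic draws from the published
additive model: 20 replicates of n = 5000 high-summer feature-days
(July–August seasons stacked so AvgTmaxLag1 spans ≈ 25–40 °C), outcome =
model prediction + Normal(0, 0.02), three iid standard-normal decoy
covariates alongside AvgTmaxLag1 and Nindex1, default `FitConfig`. Medians
over the 20 replicates of the extracted threshold knots are compared with
the generating knots (32.95 ± 0.3, 79.65 ± 0.5), and the modal importance
order must put AvgTmaxLag1 first and Nindex1 second. Problem sizes (5000
days, 20 replicates, 3000-day single-seed variants in the unit tests) are
the package's chosen desk-scale defaults; each refit takes a few seconds.

## Known limitations

* Real subgroup-specific thresholds, station-108 warning-day counts and
  raw visit totals require the undistributed surveillance and station
  data; the package reproduces their *shapes* (importance tables, yearly
  count tables, panel dimensions) and validates on synthetic data only.
* Greedy forward selection under strongly correlated covariates can place
  auxiliary knots before the dominant bend; the slope-change threshold
  rule compensates, but individual replicates can still mislocate a knot
  (medians are the supported estimator).
* The engine fits continuous responses by OLS only; generalized linear
  (count) responses are out of scope.
* Geographic station-to-center matching is out of scope; the pipeline
  assumes one weather series per center.
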