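# Methods

This note documents the models, the synthetic study system, the numerical
choices, and what the validation experiments do and do not demonstrate.

## Presence–background suitability model

The suitability model is a Gibbs/log-linear (MaxEnt-style) distribution over
background cells, `q(c) ∝ exp(λ·f(c))`, fitted by maximizing the
L1-penalized average presence log-likelihood.  Design choices:

* **Features.** Linear and quadratic terms of the five climate variables
  (annual precipitation, annual mean temperature, temperature seasonality,
  coldest-month minimum, warmest-month maximum), min–max scaled to [0, 1] on
  the background sample.  The log of a product-of-Gaussians niche is exactly
  quadratic in the variables, so this minimal feature class is
  well-specified for the virtual species while staying amenable to
  brute-force test oracles.  Hinge/product/threshold features are out of
  scope.  Elevation travels with the stack for altitude metrics but is never
  a predictor.
* **Regularization.** Per-feature penalty `β · β_LQ(m) · std(f_j) / √m`,
  where m is the presence count of the calibration sample and `β_LQ` is the
  community default schedule for the linear+quadratic feature class,
  log-interpolated through (10, 1.3), (17, 0.8), (30, 0.5), (100, 0.25).
  The global multiplier β defaults to 1.0 and is configurable.  A flat
  per-feature penalty without the class schedule was found to over-shrink
  the quadratic (curvature) terms, which leaves the fitted response
  monotone in temperature — harmless for in-sample ranking (AUC barely
  moves) but fatal for scenario transfer, because a monotone response
  inflates ranges toward the warm margin under uniform warming instead of
  translating them poleward.
* **Optimization.** Exact L1 handling via the positive/negative split
  `λ = u − v, u, v ≥ 0` with box-constrained L-BFGS-B, one warm restart
  (L-BFGS-B occasionally stops on a flat relative reduction short of
  stationarity), and an explicit KKT check: at convergence every feature
  satisfies `|E_q[f_j] − mean_pres[f_j]| ≤ reg_j` (tolerance 1e-3 before a
  convergence error is raised; the tests verify 1e-6 agreement at zero
  penalty).
* **Evaluation.** The distinct presence cells are split 4:1 into
  calibration/validation, refitted and re-scored against the fixed
  background; the split is repeated (100 times by default; the bundled
  study uses 20).  AUC is the rank statistic with ties at half weight.
  Replicates with fewer than two validation cells are skipped with a
  warning.  Species occupying fewer than ten distinct cells are not
  modelled.
* **Suitability scale and threshold.** Each replicate's surface is the
  logistic of its centered linear predictor (centered on the training
  background mean), the final surface is the replicate mean, and the
  binarization threshold maximizes sensitivity + specificity over the
  pooled validation predictions, evaluated at every distinct observed
  score with ties broken toward the lower threshold.  Presence uses the
  `≥ threshold` convention.  Projection onto other stacks reuses the
  training scaling unchanged and clamps features to the training [0, 1]
  range.

## Range, turnover and fragmentation statistics

Areas are raw grid-cell counts with no latitudinal area correction.  AC,
DSL and NDS follow the printed formulas in the README; an empty current
range is an error, while an empty future range yields AC = −100 with NDS
reported as undefined (never a silent NaN).  The geometric mean point is
the unweighted centroid of presence cells; shifts are future − current in
degrees (a great-circle km helper is provided), bearings clockwise from
north.  Altitude change is the change in mean elevation over presence
cells; min–max ranges are also emitted since reports differ on which is
quoted.  TR is masked (undefined) where NT + NC = 0.  The priority-area
criterion uses strict inequalities (TR > 50, TS > 20 by default); with
`--auto-threshold` both thresholds become half the observed maxima.
Patches use 8-connectivity by default (4 by flag); CI is computed on cell
counts, and CI change is reported as percent of the current CI, summarized
separately for declining (AC < 0) and expanding (AC > 0) species.
Cross-species Pearson correlations (area change and area-change ratio
against current position, shift components and CI change) carry two-sided
p-values; zero-variance columns yield undefined (NaN) correlations, never
0, and assemblages of fewer than three species omit the table with a
warning.

## The synthetic study system

The generator emulates the shape of a bioclimatic download without
reproducing any real dataset:

* **Terrain** (`ridge_west`): a north–south Gaussian ridge (3 500 m crest)
  in the western third over a gentle west-high slope, with the crest height
  modulated along latitude (amplitude 0.30, twelve cycles across the
  domain).  The saddle period (~1.25°) is deliberately much shorter than a
  species' latitudinal range span, so local peak geometry averages out of
  centroid shifts while saddles still cut a contracting summit band into
  disjoint patches — the fragmentation signal.
* **Climate.** Temperature falls with latitude (0.8 °C per degree) and
  elevation (6.5 °C/km) plus smoothed noise (σ 0.7 °C); the coldest/warmest
  month layers are the mean ± an annual spread tied to seasonality plus an
  independent noise term (σ 2 °C), so the six layers are correlated but not
  collinear.  Precipitation has a west–east orographic gradient;
  seasonality follows continentality (east–west).  Keeping latitude
  structure out of the scenario-static layers matters: a static layer with
  a latitudinal gradient acts as a spurious stand-in for temperature during
  fitting, and the fitted surface then fails to move under warming.
* **Scenarios** are parametric deltas on the baseline (additive °C on the
  three temperature layers, multiplicative on precipitation, additive on
  seasonality), so future-minus-baseline differences are exact by
  construction.  The default study scenario is pure +2 °C warming.
* **Virtual species** carry product-of-Gaussian niches.  The optimum is the
  baseline climate of an anchor cell; relative breadths (3, 1, 3, 1, 1)
  make species temperature-limited (precipitation and seasonality
  tolerances three times wider), and a common breadth factor is calibrated
  by bisection so the mean suitability over the grid — the expected
  suitable fraction — equals the prevalence (default 0.03).  Calibrating
  the mean rather than a hard suitability level controls the tail mass of
  the surface, which is what bounds the achievable presence–background
  AUC; prevalence was fixed by a design power check requiring the
  true-model AUC ceiling to exceed the 0.8 quality bar by more than the
  measured estimation loss of the fitted models (~0.05–0.10).  Occurrences
  are cells drawn without replacement with probability proportional to true
  suitability (one record per distinct cell), 100 per species by default.
* **Guilds and anchors.** Half the species anchor on high ground (montane:
  above the 70th elevation percentile) — cold-adapted species that contract
  upslope and fragment under warming; half anchor in warm lowlands (below
  the 30th elevation percentile, temperature between the median and the
  75th percentile).  Anchor pools exclude the northernmost quarter of rows,
  and the lowland pool's warm bound keeps each species' full response curve
  (optimum + scenario shift + tolerance) inside the environmental range the
  baseline samples — a warm-side response truncated at the margin of the
  observed data is not identifiable from presences, and models for such
  species extrapolate a monotone response that drags projected ranges
  toward the warm edge.

## What the recovery experiment shows — and does not

The bundled study (20 species, 60×60 grid at 0.25°, +2 °C, 20 replicates)
validates the full pipeline as a recovery experiment: fitted models reach
mean validation AUC above 0.8 for every species, ≈ 90 % of species show
measured poleward and upslope centroid shifts (the truth is poleward for
essentially all), montane contracting species show negative CI change, and
area change correlates positively with CI change across species.  These are
directional recoveries under known ground truth, not reproductions of any
real-world magnitudes.

Known limitations of the synthetic system: no ocean mask or irregular
coastline; climate deltas are spatially uniform, unlike circulation-model
output; occurrence records carry no spatial sampling bias, duplicates or
georeferencing error, so passing tests say nothing about robustness to
those; the domain is a single 15° square — the directional recovery
property is scale-dependent and degrades on domains much smaller than ~15°,
where terrain geometry rivals the latitudinal gradient; and with only 20
species the stochastic criteria sit close to their sampling noise (a
different seed can move the joint directional share by ±5 percentage
points, i.e. one species).

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; species k of a study uses seed
`1009·study_seed + k`.  Stage outputs are persisted as text (ESRI ASCII
grids with fixed `%.10g` formatting, CSV tables, JSON sidecars), and the
pipeline manifest records configuration, seeds, library versions and
SHA-256 hashes of every artifact; two runs of the same configuration are
byte-identical.  Degenerate inputs fail loudly: constant climate layers,
empty ranges, infeasible occurrence draws, mismatched grids or species
orderings, and unresolvable configured paths are all rejected with typed
errors before or during the owning stage.
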