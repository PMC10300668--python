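# Methods

This note documents the models and procedures implemented in `railsdm`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## The modelling problem

We model a species' habitat suitability over a planar 1 km² grid from
presence-only records plus observation-effort proxies. The records emulate
citizen-science archives: access-biased, clustered near urban areas, with
no true absences. The pipeline corrects the sampling bias, constructs
pseudoabsences from target-group effort (records of similar, detectable
taxa), fits an ensemble of four classifiers, and projects the fitted model
onto future climate covariates.

All coordinates are planar kilometres on an equal-area convention; a point
(x, y) maps to cell ⌊(coord − origin)/cell_size⌋ with half-open cell
intervals, so every point belongs to exactly one cell. Distances are
planar Euclidean; no great-circle handling is attempted, which is adequate
for region-scale equal-area projections and exact for synthetic grids.

## Synthetic landscapes (the ground truth)

Continuous covariates are Gaussian-smoothed white noise, standardized to
zero mean and unit variance over unmasked cells; the smoothing σ (in
cells) controls the autocorrelation range. Standardizing keeps the truth
coefficients interpretable on a common scale; the cost is that the
"infinitely smooth" limit is a field whose *local* variation vanishes
relative to its overall variance (lag-1 autocorrelation → 1) rather than a
literally constant layer. Categorical layers (land use, vegetation)
quantile-threshold a latent smooth field into ordered level patches, so
classes form spatially coherent mosaics.

Human population density is a constant background plus Gaussian hotspot
kernels at random centres (peak height `hotspot_intensity` people/km²,
width `hotspot_sigma_cells`). Observation effort samples cells with
replacement with probability ∝ 1 + `bias_strength` · (density / max
density), then jitters points uniformly within the cell — preserving
per-cell intensity while giving continuous coordinates for distance-based
operations. Walking effort points in draw order, each becomes a focal
presence with probability equal to the local true suitability until the
presence target is met; the rest are retained as background (other
land-bird) records. True suitability is the logistic of a linear predictor
over the standardized layers plus per-level categorical offsets; the
default truth gives human-modified classes (urban, farming,
grassland/human vegetation) positive offsets and makes `summer_precip`
the dominant (negative) driver, so recovery experiments have a known
answer.

Default conditions (one per-study choice, fixed): a 250 × 250 km grid at
1 km cells (≈ 65 000 km², the scale of the island study system this
emulates) with a masked 50 × 50 km southwest corner standing in for an
un-surveyed region; 30 000 effort points, 2400 of them presences; bias
strength 4; 12 urban hotspots of peak 200 people/km² on a 0.5 background.
These sizes reproduce the qualitative funnel of a real regional archive:
~2300 deduplicated presence cells and a pseudoabsence pool several times
larger than the final presence count.

What the generator does *not* emulate: observer heterogeneity and temporal
effort trends, detection failure (the focal species is assumed highly
detectable), spatially correlated label noise, and covariate
non-stationarity. Passing recovery tests therefore show the pipeline
recovers a known static logistic truth under urban-clustered effort bias —
not that any real archive satisfies those assumptions.

## Occurrence preparation

*Deduplication and masking.* One record per grid cell (first in input
order) and removal of records on masked cells or off-grid.

*Pseudoabsences.* Background effort records are cell-deduplicated, then
records whose cell holds a presence, or whose distance to any presence is
≤ 3 km, are removed. 3 km is the dispersal distance within which the focal
species ranges outside its territory, so closer effort cannot be read as
absence. The boundary case (exactly 3 km) is removed — the conservative
reading of "within".

*Density stratification.* The landscape is tiled into 5 km blocks
(25 km²), matched to the resolution at which census density is meaningful.
Block mean densities below 1 person/km² are excluded from threshold
estimation (they are treated as low); the threshold is the median of the
remaining block densities, and a block is high iff its density ≥
threshold.

*Thinning.* The de-clustering target is the mean presence count per
low-density block — sparsely populated areas have the least access bias,
so their record density approximates unbiased intensity. The per-block
interpretation (rather than per 1 km cell) is used because the
stratification is defined on blocks; the target is computed on the same
unit as the densities it is compared against. For each stratum the NMD
candidates (integer km, 1–10) are swept in ascending order and the
smallest candidate whose thinned density meets (≤) the target is chosen,
maximizing the number of retained occurrences; if none meets it the
largest candidate is returned flagged. A single thinning run builds the
strict within-NMD conflict graph and greedily removes a maximum-degree
point, breaking ties uniformly at random, until no conflicts remain —
the published spatial-thinning algorithm family; the result is valid (no
pair closer than the NMD) and locally maximal. Twenty resampling runs are
executed with derived seeds (run i uses seed + i) and the run retaining
the most points wins (ties to the lowest run index). On small instances
this matches the exhaustive maximum independent set almost always (the
test suite bounds the optimality gap). Presences and pseudoabsences are
thinned separately; for pseudoabsences all per-stratum NMD pairs are
enumerated and the pair whose combined retained count is closest to the
final presence count is chosen, with parity declared if the gap is within
10%.

## Ensemble modelling

Continuous features are centred and scaled on the training rows; the same
parameters are applied to any later table or raster. Collinearity is
screened by single-linkage grouping at |Pearson r| ≥ 0.7 among continuous
features, keeping per group the feature most correlated (point-biserial)
with the label; categoricals are exempt. Variable selection is backward
elimination under a random forest: at each step the current set's
cross-validated AUC is recorded and the feature with the smallest grouped
permutation importance (AUC drop when its raw column is shuffled) is
dropped; the selected set is the smallest whose CV AUC is within one
standard error of the best. The 1-SE rule is our reconstruction of "most
accurate and parsimonious"; it is isolated behind the module interface.

Members (design choices where the underlying model families leave
latitude):

* **GLM** — logistic regression with linear terms, categoricals one-hot
  encoded against a reference level, no shrinkage.
* **GAM** — logistic model with penalized smooths: a cubic B-spline basis
  (~9 basis functions per continuous feature) with an L2 penalty on the
  basis coefficients; the ridge strength C ∈ {0.1, 1, 10} is the tuned
  smoothing parameter.
* **RF** — 500 trees (100 in fast/test grids), tuned over `mtry` ∈
  {1, 2, √p}.
* **BRT** — gradient-boosted trees, tuned over learning rate
  {0.01, 0.1} × depth {2, 3}.

Each member is tuned by repeated stratified k-fold CV (k = 10; 25 repeats
by default, fewer in tests and the acceptance script — see "Problem sizes"
below) maximizing mean out-of-sample AUC, with one fold assignment shared
across the grid (stratification avoids single-class folds; the fold RNG
derives from the member seed). Ties go to the first grid point in declared
order; grid points whose fit fails are skipped with a warning. The winner
is refit on all rows. The ensemble prediction is the unweighted arithmetic
mean of the four member probabilities.

AUC is the rank statistic (probability a random presence outranks a random
absence, ties ½); TSS = sensitivity + specificity − 1 at prediction > 0.5.
The reported "model-averaged" AUC/TSS are the means of the members'
cross-validated values. Variable importance permutes one raw feature
column at a time (default 10 permutations) and scores 1 − Pearson r
between a member's predictions before and after permutation; member scores
are averaged and normalized to sum 1. A constant prediction vector (r
undefined) scores 0. Response curves sweep one feature over its observed
range (categoricals over their levels) with other continuous features at
their training mean and categoricals at their modal level.

## Projection and change accounting

Because future land-use/vegetation layers are unavailable, projection uses
a climate-only refit on the selected features minus the categorical land
layers; topography is retained as effectively constant. Future covariate
stacks add smooth offset fields to continuous climate layers (per-GCM
realisations of a scenario's mean shift, spatial texture from a smoothed
field; magnitudes halve from RCP 8.5 to RCP 4.5), leaving topographic and
categorical layers unchanged. Maps from the GCM analogues are averaged
cellwise within a scenario before change accounting.

Change per cell is Δ = (future − current) × 100 percentage points —
percentage points, not relative change, matching a 0–100 suitability
scale. Gain/loss areas use strict thresholds (Δ > 0, > 5, > 10; losses
symmetric); suitable area at threshold t counts cells with suitability
strictly > t times the cell area; range loss at t is the difference in
suitable area between current and future (negative = net gain).

## Numerical and degenerate-input choices

* All generators and fits are bit-reproducible from a single seed; derived
  seeds use fixed offsets (documented in the pipeline module).
* Zero-variance continuous features are dropped with a warning before
  preprocessing; a zero-variance feature reaching the scaler is an error.
* Thinning with NMD 0, a single point, or a conflict-free set returns all
  points without consuming randomness.
* Cell boundaries are half-open; an effort record exactly on the exclusion
  radius is removed; a block exactly at the density threshold is high.
* The run manifest contains no wall-clock state so that identical seeds
  produce bit-identical manifests.

## Problem sizes used in tests and the acceptance rerun

The library defaults (25 CV repeats, 500-tree forests) reflect the full
analysis. The test suite and `scripts/acceptance.py` run the same code at
reduced cost as the package's own choice of desk-scale experiment: 1–3 CV
repeats, 80–200 tree forests, and (in unit tests) smaller grids; the
recovery experiment uses a 60 × 60 km landscape, n = 600 balanced points,
a dominant truth coefficient of 3.0 and 20 seeds. Quantities that depend
only on the data preparation (funnel counts, NMD tuning, parity) are exercised
at the full default conditions.

## Known limitations

* The NMD tuning reproduces the published procedure's *rule* (smallest
  distance meeting the low-density target) but the original tool's exact
  resampling internals are not printed anywhere; the greedy max-degree
  reconstruction is bounded against exhaustive search only on small
  instances.
* The correlation-metric importance is a reconstruction of the cited
  implementation's documented behaviour, not a line-by-line port.
* Random (non-spatial) cross-validation folds overestimate transferable
  skill under spatial autocorrelation; spatial-block CV is out of scope.
* Pseudoabsence parity is limited by the integer NMD grid; on small
  landscapes the retained-count steps between candidate distances can
  exceed the 10% tolerance.
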