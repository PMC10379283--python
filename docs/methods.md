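# Methods

## Scope and data model

`ratdiv` treats compiled population-level records of observed
heterozygosity (Ho) as point observations on a global WGS84 lat/lon grid of
five anthropogenic predictors. Ho is the only diversity metric used: it is
directly comparable across source studies and, unlike expected
heterozygosity, does not assume Hardy–Weinberg equilibrium, which several
compiled rat datasets violate. Only nuclear markers (microsatellites, SNPs,
RAD-seq) are accepted; mitochondrial records are rejected at parse time
because haploid, uniparental markers yield Ho values that are not
commensurable with diploid nuclear Ho.

Rasters are represented as north-up rectilinear grids with NaN as the
in-memory nodata value and ESRI ASCII grid (`.asc`) as the on-disk format —
a plain-text interchange format every GIS reads, which keeps the artifact
fully inspectable. Inputs are required to be WGS84 geographic already;
reprojection from arbitrary CRSs is out of scope.

## Harmonization and extraction

All layers are resampled to a common cell size (2.5 arcmin ≈ 5 km at the
equator by convention) with nearest-neighbour lookup: each output cell takes
the value of the source cell whose center is nearest its own center. Nodata
propagates unchanged and is never interpolated. Ties (an output center
equidistant between source centers) resolve to the smaller row, then the
smaller column — an arbitrary but documented and tested convention.

Point extraction uses half-open cell membership, [left, right) in longitude
and (top, bottom] in latitude, with the grid's own north edge included in
the first row; a point at longitude 180 wraps to −180. Coordinates are
point locations, not buffered neighbourhoods. A locality outside the grid
or on nodata in any single layer is dropped and counted (complete-case
analysis; no pixel is imputed), so `input = retained + dropped` holds at
every stage and is asserted in the run report.

## Descriptive statistics

* **Correlation screen** — Pearson r of each predictor against Ho with the
  two-sided t-test p-value; a constant column yields NaN with a warning
  rather than an error, so one degenerate layer cannot kill a run.
* **PCA** — variables are centred and scaled to unit (population) variance,
  then decomposed by SVD; loadings are orthonormal and explained fractions
  sum to 1. Ho is an active variable by default; `include_ho=False` demotes
  it to a supplementary variable, since either reading of "PCA over Ho and
  the predictors" is defensible.
* **HCPC** — Ward-linkage agglomerative clustering on the scores of the
  components with explained variance ≥ 1/p (a Kaiser-like rule on
  standardized data; at least one component is always kept). When k is not
  given it is searched over 2..10 and chosen where the inertia gain of the
  split dwarfs the next one (largest gain ratio) — the elbow of the
  within-cluster inertia curve.
* **Island vs mainland** — two-sided Wilcoxon rank-sum on Ho. Exact null
  enumeration when both groups have ≤ 10 records and the pooled values are
  tie-free; otherwise the normal approximation with tie correction. When
  every pooled value is identical the test is defined as p = 1 (no evidence
  either way) instead of a division-by-zero.

## Random-forest regression

Forests are bagged regression trees with `max_features = 2` (⌊√5⌋) and
`min_samples_leaf = 5` — standard regression-forest defaults — and a fixed,
recorded seed. Three quantities matter:

* **OOB RMSE.** Out-of-bag predictions average, per record, the predictions
  of the trees whose bootstrap draw excluded that record. The bootstrap
  bookkeeping is cross-checked in the tests against scikit-learn's own OOB
  predictions to machine precision. Records sampled by every tree (possible
  for very small forests) are excluded from the RMSE rather than filled
  with a default; the covered fraction is reported.
* **Tree-count search.** One forest per candidate size in a strictly
  increasing grid within [10, 10000] (default {10, 25, 50, 100, 250, 500,
  1000, 2500, 5000, 10000}: log-ish spacing balances cost and resolution),
  same seed throughout; the minimum-OOB-RMSE fit wins, ties going to the
  smaller forest. Per-candidate RMSEs are kept in the run report.
* **Importance.** Impurity (variance-reduction) importance summed over the
  forest — the regression analogue of the Gini index — then divided by its
  maximum so the top predictor scores exactly 1. Max-normalization is the
  only scaling under which an importance table has one entry of exactly 1
  per species, which is how such tables are naturally compared across
  species. An all-zero importance vector (constant response) is refused by
  `normalize_importance` rather than silently rescaled.

**Jackknife validation.** With fewer than ~100 records per species, each
record is predicted by a forest fitted on the other n−1 (leave-one-out,
no replacement). Refits reuse the grid-search winner's tree count rather
than re-searching (the search costs n times more and the optimum is flat).
Records are processed in a canonical order (sorted by coordinates, study,
site, Ho) with per-record seed `base + position`, which makes the held-out
predictions invariant to input row order. Reported: held-out RMSE, and the
R² and p-value of the least-squares regression of observed on predicted Ho.

## MESS and the validity mask

The univariate similarity is the canonical piecewise formula (0–100 inside
the reference range, 100 at the reference median, negative outside the
range) with f counted as the percentage of reference values *strictly*
below the query value; MESS is the cell-wise minimum over the five
predictors, computed against the same localities that trained the forest.
The implementation is vectorised via sorted-reference binary search and is
required by the acceptance tests to match an independent double-loop
evaluation to 1e−9 on randomized instances. A constant reference variable
makes the formula undefined and raises.

The default mask keeps cells with MESS strictly greater than the median of
the strictly positive MESS cells. Note this discards roughly the lower half
of even the non-extrapolated area — a deliberately conservative rule, kept
as the default because it is the one the projection workflow is defined
with; `rule="nonnegative"` exposes the milder conventional alternative
(keep all MESS ≥ 0). The median of an even count is the midpoint of the two
central order statistics; cells exactly at the threshold are excluded.

## Projection

The fitted forest is evaluated at every cell with complete predictors and
mask approval; everything else is nodata (−9999 on disk). Both the masked
and unmasked surfaces are written so the cost of the mask can be inspected.
Because forest predictions are averages of leaf means, every finite
projected cell lies within [min, max] of the training Ho; this is asserted
on every synthetic run.

## Synthetic data

The generator emulates the statistical shape of real socioeconomic
surfaces, not their content: each predictor is a seeded sum of 10 Gaussian
bumps with centers uniform over the extent and widths of 2–10% of the
extent (sub-continental structure — smooth at the working resolution yet
mutually weakly correlated between layers; measured mean pairwise |r| ≈
0.18), standardized to zero mean and unit variance over valid cells, with
nodata carved out in contiguous circular blobs. Localities sit at centers
of cells valid in all layers, and

```
ho = clip(intercept + Σ_v beta_v · x_v + island_effect · 1[island] + N(0, noise_sd), 0, 1)
```

Defaults mirror the compiled rat data: 80 localities per species, island
fraction 0.3, intercept 0.55 (0.62/0.45 for the two species in the
`simulate` command, matching their relative diversity levels), noise sd
0.05 Ho units, island effect 0.05, and beta = (0.03, **0.10**, 0.03, 0.02,
0.03) so population density carries the dominant effect. Clipping (rather
than a logistic transform) enforces the [0, 1] bounds because it keeps the
inverse reasoning in recovery tests simple; with large effects it visibly
attenuates linear correlations (an effect of 0.5 Ho/sd saturates about a
third of the mass), which the tests account for.

What passing tests on these data do **not** show: real predictor surfaces
are heavy-tailed and cross-correlated in structured ways (wealth and travel
time are not independent), real Ho is spatially autocorrelated through
shared colonization history, and real sampling is biased toward cities of
the global North. The generator makes the machinery testable; it does not
validate the biology.

* **Noise-floor scenario** (acceptance): a single learnable effect
  (beta₁ = 0.15) under noise sd 0.05 at n = 100, so the jackknife RMSE
  should approach the noise sd from above; a multi-predictor signal would
  confound the floor with model bias.
* **Recovery scenario** (acceptance): beta = (0.5, 0, 0, 0, 0), noise sd
  0.01, n = 200 — a dominant effect the forest must rank first.

## Orchestration and reproducibility

`run_all` executes, per species: extract → correlations → PCA/HCPC →
Wilcoxon → tree search → jackknife → MESS → mask → projection. A stage
failure marks that species failed with a machine-readable record; other
species continue. All randomness flows from the single config seed via
`stage_seed` (CRC32 of `"species:stage"` XOR seed, reduced below 2³¹), and
the JSON report carries no timestamps, so identical configs produce
byte-identical reports — asserted in the tests.

Problem sizes in the test and acceptance runs (grids of 20×40 to 45×90
cells, 30–200 localities, tree grids up to 1000) are scaled-down study
conditions chosen to exercise every code path at interactive cost; the
statistical contracts they check (oracle agreement, noise floor, recovery
rate, determinism, bounds) are size-free.

## Known limitations

* No spatial-autocorrelation correction: samples are treated as
  exchangeable, as the sparse, uneven global sampling of compiled rat
  studies does not support spatial thinning.
* No reprojection: inputs must already be geographic WGS84.
* No per-cell uncertainty on the projection, and no permutation importance
  (impurity importance is biased toward high-cardinality predictors; with
  five continuous predictors on one scale this bias is immaterial).
* The antimeridian is handled for point extraction, but bump fields are not
  periodic in longitude.
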