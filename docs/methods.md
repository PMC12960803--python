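# Methods

This note records the statistical and numerical choices behind `lcfusion`:
what each component assumes, which knobs matter, and what the synthetic
benchmarks do and do not demonstrate.

## Rasters and grids

All rasters are single-band, north-up grids with pixel-center semantics:
cell (row, col) has its center at (origin_x + (col+½)·dx, origin_y −
(row+½)·dy).  Rasters carry an opaque CRS tag compared for equality only;
no reprojection is implemented — inputs must already share a metric CRS
and grid.  Nodata propagates: nodata cells are excluded from every tally,
and an operation on an all-nodata pixel yields nodata.  GeoTIFFs are
written with the standard georeferencing tags (ModelPixelScale,
ModelTiepoint, GDAL_NODATA); nearest-neighbour resampling assigns each
output cell the value of the source cell whose *center* is nearest the
output cell center, so it can never invent values.

## Legend harmonisation

Crosswalks are data, not code: CSV tables with one row per source code,
validated so that no source code maps to two harmonized codes
(many-to-one is fine; a source class spanning two harmonized classes is
rejected).  The six shipped crosswalks pair each product's public legend
codes with the 9-class harmonized scheme; products lacking a class (e.g.
CLC+ Backbone has no wetland class) simply never produce that code.
Multi-year stacks are aggregated by per-pixel mode; mode ties break to the
lowest class code — deterministic and independent of the stacking order.

## Validation design

The total sample size targets a standard error on overall accuracy:

    n = (Σ_h W_h S_h / SE_target)²,   S_h = √(UA_h (1 − UA_h)),

where W_h is stratum h's area share and UA_h the accuracy expected inside
it.  Default SE target 0.01; default floor 70 points per stratum.  Points
are allocated proportionally to W_h (largest-remainder rounding), raised
to the floor, and the surplus is taken back from the largest allocations
proportionally, never below the floor and never letting the total drop
under the computed n.  Strata come from an external stratification map and
are deliberately decoupled from the evaluated maps' classes.

Reference labels: several interpreters per point, adjudicated by strict
majority (> half the labels present); failing that, a flagged
confident-single-expert override; otherwise the point is marked
unresolved, logged, and excluded from estimation.

## Accuracy estimators

Rows of the error matrix are map classes, columns reference classes, so
user's accuracy is row-conditional.  With n_hij counts per stratum, cell
proportions are p̂_ij = Σ_h W_h n_hij / n_h.  OA is a stratified mean of
the per-point correctness indicator with variance Σ_h W_h² s²_yh / n_h;
UA/PA are ratio estimators with the linearised variance

    V(R̂) = Ŷ⁻² Σ_h W_h²/n_h (s²_xh + R̂² s²_yh − 2 R̂ s_xyh),

x and y being the numerator/denominator indicators.  In a single stratum
these collapse to SE(OA) = √(OA(1−OA)/(n−1)).  Because the variance
algebra is easy to transcribe wrongly, a stratified bootstrap (resampling
points within strata, B ≥ 100) is kept in the package purely as an
independent cross-check; the test suite requires the analytic SE(OA) to
sit within 15% of a 2 000-replicate bootstrap on three designs.  Classes
absent from the sample report missing (NaN) UA/PA/F1 rather than zero.

## Consensus rules

All three rules share tie-breaking: larger number of supporting datasets
first, then lowest class code — deterministic and invariant to dataset
ordering.  Pixels where every member is nodata stay nodata.

* **Weighted voting.** score(c) = Σ_{d: a_d=c} F1[d,c].  With all-equal
  weights this reduces exactly to majority voting (verified by brute-force
  enumeration).
* **Accuracy–confusion.** score(c) = Σ_{d: a_d=c} q_d(c|c) −
  Σ_{d: a_d≠c} q_d(c|a_d), with q_d the row-normalised (mapped-class
  conditional) confusion of member d estimated from the validation sample.
  Scores may go negative; the argmax is taken over raw scores because
  clamping would discard the penalty structure.  The conditioning
  direction of the penalty term is a genuine modelling choice; a
  `variant="column"` switch draws the penalty from the column-normalised
  matrix instead.  Row-normalised is the default: it is the reading under
  which agreement is rewarded in proportion to a member's reliability for
  the class it voted.
* **Random-forest stacking.** Each member's vote becomes a sparse D×C
  block feature holding F1[d,c] at the voted class; a 500-tree forest
  (library defaults otherwise, fixed seed, single thread) is trained on
  labeled points and predicts every pixel with at least one vote.
  Training classes with fewer than two points raise.  Weights for a class
  a member never maps are zero and flagged, so empty rows cannot inject
  spurious evidence.

## Terrain

Slope and aspect use the Horn 3×3 operator (the common GIS default) with
edge replication at borders; slope = arctan √(gx²+gy²) in degrees, aspect
= compass bearing of the downslope direction (east-rising plane → 270°,
north-rising plane → 180°).  Flat cells carry an undefined-aspect sentinel
and are excluded from aspect histograms rather than binned.  Aspect roses
use 8 sectors with N = [337.5°, 22.5°).  Derivatives are computed at the
DEM's native grid and the derived surfaces resampled afterwards; the DEM
may equally be resampled first — both orders are available because the
right choice depends on the DEM's native resolution relative to the maps.

## Landscape metrics

Buffers: regular lattice at 5 km spacing with 2 500 m radius (tangent,
non-overlapping); buffers touching the extent boundary are retained,
buffers crossing it are dropped.  Patches are 8-connected components
(4-connectivity available) clipped to the circular mask.  Edge density
counts class/non-class shared cell edges inside the window only — edges
created by clipping a patch at the window boundary are excluded by
default (a documented switch includes them), since a buffer sliced through
a large meadow has no real edge there.  PAFRAC = 2 / slope of the
least-squares regression of ln(area) on ln(perimeter) across patches:
exactly 1 for families of similar squares (P ∝ √A), approaching 2 for
highly convoluted shapes; reported missing with fewer than two patches of
distinct size.  Window area is the discretized mask area (cell count ×
cell area), so closed-form edge-density checks use the same discrete area.

## Synthetic landscapes

The generator's defaults describe the study regime the package targets:

* **Truth maps** — per class, a Gaussian random field smoothed to a
  correlation length (default 8 cells) and standardized; per-class offsets
  are calibrated iteratively until realized shares are within ±0.03 of the
  requested mix.  The default mix is grass-heavy
  (0.06, 0.16, 0.26, 0.08, 0.25, 0.07, 0.04, 0.04, 0.04) — a mountain
  mosaic dominated by forest, grassland and cropland.
* **Ensemble members** — each cell's observed class drawn independently
  from the row of a known C×C confusion matrix; distinct streams per
  member make errors conditionally independent given the truth, the
  regime in which consensus provably helps.  The default six members have
  per-class diagonal accuracies spanning 0.6–0.95, with two members given
  0.55–0.65 grassland recall (the "global products under-detect
  grassland" pattern).  A patchy-error variant (errors in contiguous
  blobs) exists for stress tests only; the estimator math assumes
  point-level independence.
* **DEM** — smoothed Gaussian surface scaled linearly to a relief
  amplitude (default 1 500 m over a 500 m base).

What passing tests show — and don't: the benchmarks certify the
estimators and fusion rules under conditional independence and
spatially-uncorrelated label error.  Real products share sensors and
training data, so their errors correlate; consensus gains on real
ensembles will be smaller than on these fixtures, and the accuracy
estimators (which are design-based, not model-based) remain valid but the
consensus-improvement guarantees do not transfer automatically.

## Benchmark problem sizes

The consensus-improvement benchmark uses 512×512 cells, six members, nine
classes, 5 000 validation points, 2 000 training points, 10 000 held-out
cells, ten seeds.  The estimator-recovery benchmark uses a four-class,
high-agreement regime (diagonals 0.93–0.96, equal allocation of 5 000
points over map-class strata, so each class receives 1 250 points and the
per-class sampling SE ≈ 0.007): this makes a ±0.02 recovery band a ~2.8σ
statement that a correct estimator passes with high probability, while a
biased one fails.  Recovery is judged against the exact full-population
accuracy of the realized corrupted map, computable because the generator
holds the truth — so only sampling error, not Monte-Carlo error in the
target, enters the comparison.  Standard-error calibration uses three
designs (one, two and three strata; 500–600 points) against a
2 000-replicate stratified bootstrap.

## Known limitations

No reprojection, mosaicking or tiled processing; inputs must be pre-aligned.
Per-pixel class-probability surfaces are not produced.  Area estimates with
confidence intervals for class extents are out of scope (proportions are
reported descriptively).  The AccCo penalty's conditioning direction is a
documented switch, not a resolved question.  Crosswalk code values follow
the products' public legends; users whose rasters encode legends
differently should supply their own CSV.
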