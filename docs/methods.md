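# Methods

`ecorisk` implements a probability-loss ecological risk assessment for
geological disasters (landslides, collapses, debris flows) as a raster
pipeline:

```
Risk = Hazard x Vulnerability x Damage
```

computed cell-wise on a shared projected grid.  Hazard is the probability-like
component (how likely is a disaster here), vulnerability describes how fragile
the local ecosystem's structure is (how badly a disturbance propagates), and
damage is the exposure term (how much ecosystem service and population there
is to lose).  This note records the model choices, parameter defaults, and
numerical conventions, and what the synthetic test region does and does not
establish.

## Spatial model

All layers share a `GridSpec` (rows, columns, square cell size in meters,
top-left origin, CRS tag).  Co-registration is enforced by exact equality of
these fields; combining layers on different grids is an error, not a silent
resample.  Points are assigned to cells by `floor((x - origin)/cell)`, so a
point on a shared edge belongs to the cell to its right/below.  Areas are
`cell count x (cell/1000)^2` km² — projected CRS assumed, no geodesic
correction.  Rasters travel as single-band GeoTIFFs (float32 continuous with
NaN nodata, uint8 categorical with code 255 reserved), written and read via
tifffile with the standard geo tags; masked cells are excluded from every
statistic.

## Hazard

**Training set.**  The disaster inventory is split 70/30
(train/validation) with the training size rounded half-up.  Negatives are
drawn uniformly, without replacement at cell granularity, from cells whose
centers lie at least `buffer_m` from every disaster point and off river
cells.  The buffer default is 500 m, the value appropriate to a
province-scale inventory (thousands of points over ~10^5 km²); the synthetic
pipeline uses 100 m because on its ~8 km region 500 m buffers around hundreds
of events would leave no background at all.  Exclusion is exact at
cell-center granularity, which makes it testable by brute force.

**Random forest.**  Nine conditioning factors in fixed order: elevation,
slope, precipitation, NDVI, aspect, land use, lithology, distance to fault,
distance to river.  Categorical factors (land use, lithology, aspect
sectors) enter as integer codes so the feature count stays at nine and
`max_features = 5` keeps its meaning; aspect is circular and is encoded as
9 sectors (8 compass octants + flat).  Hyperparameters (number of trees,
features per split) are chosen by grid search on out-of-bag error, with ties
broken toward fewer trees then fewer features; the operating default is 100
trees and 5 features.  Accuracy is additionally reported from seeded
stratified 5-fold cross-validation.  Factor importance is the normalized
mean impurity decrease.  Note its known cardinality bias: a continuous noise
feature can legitimately outrank low-cardinality categorical codes, so
importance comparisons in the tests are made against the truly informative
factors, not against the categorical decoys.

**Information-value baseline.**  For factor *j* binned into classes *i*,

```
IV_ij = ln[ (N_ij / N) / (S_ij / S) ]
```

with N the disaster total, S the unmasked cell total, and the cell score the
sum of its bins' IVs over all factors.  Continuous factors use natural-breaks
bins (8 by default); categorical factors use one bin per class.  Bins with
zero disasters get a half-count continuity floor, `ln[(0.5/N)/(S_ij/S)]`,
instead of −∞.  The score is unbounded and is flagged as a score, not a
probability; it is range-standardized before entering the risk product.

**Validation.**  AUC is the rank (Mann–Whitney) statistic with tie
correction, computed against held-out disaster points and freshly drawn
negatives; the implementation and the exhaustive concordant-pair oracle in
the tests are independent routes.  Frequency-ratio analysis overlays the
validation points on the five-level classified map and reports, per class,
area (km²), count, proportion of points (%), and frequency.  **Frequency is
disasters per 100 km²** (`count/area x 100`): published per-class tables of
this kind print values consistent only with that scaling even where the
header nominally reads "/km²", and this package documents and uses the
per-100 km² convention explicitly.

## Vulnerability

On an analysis grid (0.5 km cells by default; fine cells are assigned by
center, edge cells keep their true area) each cell's land-cover mosaic yields:

- patch density `PD = patches / A` (patches per km², 8-connectivity by
  default, switchable to 4);
- division `DIVISION = 1 − Σ_patches (a_p/A)²`;
- fragmentation `C_i = N_i / A_i`, separation
  `S_i = (A / 2A_i) · sqrt(N_i / A)`, dominance
  `D = ln m + Σ_i (A_i/A) ln(A_i/A)`;
- disturbance `LDI = 0.5·C + 0.3·S + 0.2·D`, where the class-level C and S
  are aggregated to the cell by area weights `A_i/A` first.

The separation form follows the standard landscape-ERA usage with `n_i`
taken equal to the class patch count `N_i`; both choices are isolated in one
function so an alternative form is a drop-in.  LDI, PD and DIVISION are
range-standardized **globally across all analysis cells** and averaged into
`VI = (LDI + PD + DIVISION)/3 ∈ [0, 1]`, then classified into five
natural-breaks levels.  A single-class cell gives exactly `D = 0` and
`DIVISION = 0`; a completely uniform region gives `VI = 0` everywhere and no
five-level map (there is nothing to classify).  An advisory warning (never an
error) flags analysis cells outside 2–5x the average patch size.

## Damage

Three ecosystem services proxy the potential ecological loss:

- **Water conservation** (m³/a per cell): `(P − R − ET) x 1e-3 x cell area`,
  clamped at zero — a conservation service cannot be negative.  Surface
  runoff R is not usually observed, so it is derived as
  `R = coefficient(land cover) x P` with handbook-magnitude defaults
  (forest 0.10 … built-up 0.70, water 1.0), all configurable.
- **Soil conservation** (t·hm⁻²·a⁻¹): RUSLE gap between potential and actual
  erosion, `SOR = R·K·LS·(1 − C·P)`.  LS uses flow-path slope lengths
  (steepest-descent accumulation, capped at 120 m, initialized at one cell
  size on divides), `L = (λ/22.13)^m` with the exponent piecewise in slope,
  and the McCool piecewise S equations.  The vegetation factor is
  `C = exp(−2·NDVI/(1 − NDVI))`, clamped to [0, 1] with C = 1 for NDVI ≤ 0;
  the management factor P is a land-use lookup (cropland 0.35, water and
  built-up 0, else 1).  All three formula choices sit behind configuration so
  alternative LS/C forms are drop-ins.
- **NPP** enters directly: lush vegetation means more productivity at risk.

The three services are range-standardized and summed into the ecological-loss
layer; that layer, standardized again, is added to standardized population
exposure and the sum rescaled to [0, 1].  The additive overlay is the
simplest combination consistent with presenting ecological loss, population
and total as separate then combined surfaces; because range standardization
is affine-invariant, a constant (information-free) layer contributes exactly
zero, with a warning.

## Risk composition

Risk is the unweighted cell-wise product of hazard, vulnerability and damage,
each in [0, 1].  Hazard enters as the continuous RF probability rather than
its 5-level class rank — this avoids classification artifacts; a class-rank
alternative is available for sensitivity runs.  The coarse VI surface is
upsampled by nearest-cell assignment so every fine cell inherits its analysis
cell's value, preserving the analysis-unit semantics.  The product is
classified into five natural-breaks levels and reported with per-class area
percentages and a disaster frequency table.

## Natural breaks

Classification everywhere uses exact Fisher–Jenks: the dynamic program
minimizing total within-class sum of squared deviations, with ties broken
toward the earliest feasible split.  Intervals are lower-open/upper-closed
(a value equal to a break belongs to the lower class).  The DP is quadratic,
so rasters with more than 10,000 unmasked cells are classified from a seeded
subsample; on well-separated distributions the subsampled breaks classify
≥ 99% of cells identically to full-data breaks (asserted in the tests).

## The synthetic region

Real inputs for this pipeline are a DEM and a dozen derived or remotely
sensed layers that cannot ship with a package.  The generator produces a
fictitious mountain region, deterministic in (config, seed):

- terrain by spectral synthesis (power-law filtered Gaussian noise, default
  exponent 1.8, relief 1200 m, 256x256 cells at 30 m);
- rivers by steepest-descent traces from seeded high-elevation cells (not
  full flow-accumulation hydrology — sufficient to create valley-correlated
  factors), faults as random chords, distances via exact Euclidean distance
  to the polylines;
- precipitation = 1400 mm/a + 0.15 mm/a per m of elevation + correlated
  noise (sd 150 mm/a).  The moderate lapse and strong mesoscale noise keep
  precipitation from collapsing onto elevation, so each factor carries
  identifiable signal of its own;
- NDVI increasing with precipitation and suppressed where development sits;
  land cover by a covering threshold cascade over the seven classes;
  lithology as a five-group Voronoi mosaic; population concentrated on low,
  flat ground; NPP coupled to NDVI; ET consuming part of precipitation;
  erosivity scaling with rainfall and erodibility with lithology.

**Planted truth.**  The disaster inventory samples cells without replacement
with probability proportional to
`sigmoid(−3 + 10·slope′ + 6·precip′ − 8·NDVI′ − 5·elev′)` (primes are
range-standardized layers), 800 events by default.  The strong coefficients
are deliberate: the planted process must be *recoverable* — a trained hazard
model should rank the weighted factors above the zero-weight decoys and
reach held-out AUC ≥ 0.75 — and weak or collinear signal makes recovery
statistically impossible at this region size.  Because weights are recorded
next to the inventory, recovery is a testable property, not an assumption.

**What passing tests show — and don't.**  The synthetic region validates the
machinery: co-registration, exact formulas, exclusion rules, determinism, and
the qualitative behavior of the full chain (frequency rising with hazard
level, risk concentrating at event cells).  It does not emulate real
landslide physics, real spatial autocorrelation structure, inventory biases,
or mapping errors, so test performance (e.g. AUC ≈ 0.85) says nothing about
performance on real regions.

## Problem sizes and numerics

The test suite uses 64–128 cell regions for unit tests and ten seeded
256x256 regions (800 events each) for the recovery properties; the
acceptance script runs one full 256x256 pipeline plus the information-value
baseline, a few minutes end to end.  All stochastic steps derive from one
pipeline seed through named `SeedSequence` streams, so stages are
independently reproducible; reruns with the same config are bit-identical.

## Known limitations

- Impurity-based importance is cardinality-biased (see above); permutation
  importance would be fairer to categorical factors but is not what the
  reported ranking uses.
- The runoff coefficients, RUSLE LS/C forms and the additive damage overlay
  are standard choices, not fitted to any region; swap them via configuration
  when calibrating to real data.
- No reprojection: all inputs must already share a projected CRS and grid
  (resampling between grids in the same CRS is provided).
- Uncertainty and sensitivity analysis of the composed index are out of
  scope.
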