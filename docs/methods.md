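# Methods

This note documents the models, numerical choices and limitations of
the `ems_access` pipeline in the order the stages run.

## Synthetic city

The generator emulates the inputs a real ambulance-accessibility study
draws from external sources: a gridded population product, station
point locations, administrative districts with a central/suburban
split, and driving times from a commercial routing API sampled at
several times of day.

* **Population** is a two-component exponential-decay surface (a tight
  urban core, decay range 0.15 of the city extent and weight 0.6, plus
  a broad tail, range 0.6 and weight 0.4, centered on a slightly offset
  second core) multiplied by lognormal noise (σ = 0.3) and scaled to a
  total of 1.2 M people on a 50 × 50 grid of 250 m cells. This produces
  the monotone center→periphery density gradient real cities show
  without reproducing any particular city.
* **Districts** are Voronoi cells of uniformly drawn seed points; the
  3 (of 8) seeds nearest the city center form group 1 ("central"), the
  rest group 2 ("suburban"). This is a deliberately simple, reproducible
  zoning; it does not guarantee that the central group exactly coincides
  with the high-accessibility zone the way hand-drawn administrative
  boundaries in a monocentric metropolis do.
* **Stations** are drawn without replacement with probability
  proportional to population², concentrating them in the core — the
  center-heavy station layout (hospitals and health centers) whose
  consequences the analysis is designed to expose. The default is 20
  stations.
* **Speeds** are a smooth radial field from 200 m/min (12 km/h) in the
  congested core to 400 m/min (24 km/h) at the periphery — *effective*
  door-to-scene speeds, deliberately below posted road speeds. One field
  per traffic period, scaled by congestion multipliers 1.0 / 0.85 /
  0.75 / 0.65 for 00:00, 12:00, 16:00 and 18:00. Because a period is a
  uniform rescaling, travel times are exactly monotone in congestion —
  a property the tests exploit.
* **Travel-time oracle.** Driving time is the least-time path over the
  8-connected grid graph: moving between adjacent cell centers costs
  distance ÷ harmonic-mean speed (equivalently, half of each cell is
  traversed at that cell's own speed); diagonal steps are √2 longer.
  8-connectivity keeps the grid metric within ~8 % of Euclidean.
  The oracle is treated as exact; it has no model of the routing error a
  web API would add, so tests validate internal consistency, not
  robustness to noisy travel times.

All randomness flows from one `numpy` generator seeded by the config,
so a fixed seed reproduces the city bit for bit.

## Travel times and response field

Each destination cell is matched to its k = 3 nearest stations by
planar straight-line distance (ties to the lower station id) and the
oracle is queried per pair and period; the cell's response time is the
minimum driving time plus a 2-minute dispatch offset (the
call-to-departure time; a national guideline caps it at 3 min, and a
well-run metropolitan system is assumed to beat that). k-nearest
preselection by air distance is an approximation — the air-nearest
station need not be time-nearest — and with k equal to the station
count it vanishes; the suite asserts that exact equality.

## Accessibility surface

The 250 m response samples are interpolated to 100 m by **ordinary
kriging** with a single semivariogram (exponential model by default,
fit to a binned empirical semivariogram of up to 2000 subsampled
points; linear fallback if the fit fails) and a moving neighborhood of
16 samples. The nugget defaults to 0, which makes the predictor honor
its samples exactly. An optional linear drift removes a least-squares
plane first; an IDW mode exists as a robust fallback. Predictions are
clipped into the sample range, which preserves the dispatch-time floor
despite negative kriging weights. This is an open, documented stand-in
for the proprietary empirical Bayesian kriging of commercial GIS —
the ensemble-of-variograms machinery is not reproduced, only the
intent: smooth spatial prediction of response times.

**Focal outlier rule.** A cell deviating from the mean of its 3 × 3
neighbors (the cell itself excluded — with the center included a 3 × 3
window can never flag at z = 3) by more than 3 neighborhood standard
deviations is replaced by that mean. The rule touches only flagged
cells and is idempotent on a clean surface. Window and threshold are
declared defaults, not empirical estimates.

**Population mask.** Population is resampled between grids by 1-D
area-overlap weight matrices (people are extensive; mass within the
shared extent is conserved to floating-point error) and cells with zero
resampled population are masked out of every statistic.

Raster convention throughout: one planar CRS in meters, row 0 at the
north edge, values at cell centers.

## Indicators, equity, partitioning, overlap

* PRT and coverage are computed on the raster directly; polygons are
  export-only, avoiding vectorization artifacts. Threshold comparison
  is closed (R ≤ t): a cell at exactly 12.0 min counts as covered.
* The Theil index uses natural logarithms on district-level aggregates.
  Zero indicator values (a district with 0 % strict coverage) take the
  continuous-extension limit Y ln Y → 0 with a warning. Components
  satisfy T = T_WG + T_BG to ~1e-15; the suite enforces 1e-10.
* Impedance is 60·|∇R| s/100 m with ∇ estimated by central differences
  (one-sided at edges; masked cells nearest-filled before
  differencing), floored at 1 s/100 m so the cost graph stays positive
  at stations, where the gradient of a least-time field vanishes. The
  gradient reading of the surface-parameters step is the only one
  consistent with the stated unit.
* MCR allocation is a per-station Dijkstra over the same 8-connected
  graph (edge cost = step length × mean impedance of the two cells,
  matching the oracle's half-cell convention), with ties to the lower
  station id and unreachable cells flagged rather than dropped. The
  model comparison regresses accumulated cost against oracle driving
  time by ordinary least squares, per period, on all valid cells, and
  reports R² and RMSE for the heterogeneous raster and for a
  homogeneous raster fixed at its spatial mean.
* Per-station isochrones sample destinations within a planar 8 km
  radius (wide enough to contain a free-flow 15-min isochrone at the
  default speeds) and reuse the 2-min dispatch offset. Overlap counts
  above 20 map to the top class with a warning.

## Problem sizes

The default demo city is 50 × 50 cells at 250 m (12.5 km side, 15 625
output cells at 100 m). The validation suites use 16–30-cell cities,
100 random grids up to 20 × 20 for the shortest-path cross-check, 1000
random district tables for the Theil identity, and 20 seeded cities for
the cost-model contrast — sizes at which the independent brute-force
oracles are exact and fast while every structural property (gradient,
congestion ordering, group contrast) is already present.

## Known limitations

* The grid-graph oracle approximates road-network routing; absolute
  travel times have no empirical calibration, so results are
  structurally, not numerically, comparable to any real city.
* Random Voronoi districts give a weaker central/suburban separation
  than real administrative zonings; the between-group share of the
  Theil index in generated cities is correspondingly conservative. The
  suite demonstrates between-group dominance on an explicit two-ring
  zoning instead.
* Dispatch time is a constant, not a distribution; on-scene, transport
  and return phases are out of scope.
* Kriging with a global variogram underestimates local heterogeneity
  relative to ensemble methods; for strongly non-stationary fields the
  IDW mode may be preferable.
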