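# Methods

This note documents the models implemented in `ecoscape`, the choices made
where the standard formulations leave room, and what the synthetic-data
tests do and do not establish.

## Land-cover accounting

The transition matrix S_ij holds the area (km²) of cells carrying class i
at the first date and j at the second, over the *jointly valid* extent:
cells that are nodata in either epoch are excluded from both marginals, so
row sums equal first-epoch class areas, column sums equal second-epoch
areas, and the grand total equals the jointly valid area. Change rates are
`100·(a₂ − a₁)/a₁` and are reported absent (NaN) for classes with no
first-epoch area. Trajectory rasters encode the class pair as `10·i + j`
(farmland→forest = 12; unchanged forest = 22), which restricts the scheme
to single-digit class codes — adequate for the seven-class legend.

Grid convention: row-major, origin at the top-left cell corner, centres at
`origin + (k + 0.5)·cell_size`, y down. Two grids are co-registered when
shape matches and cell size/origin agree within 1e-6 of a cell, absorbing
float geotransform noise. Cell area is `cell_size²/10⁶` km².

## Habitat quality

### Degradation

For each threat r with weight ω_r, maximum effective distance d_max and
decay form (linear `1 − d/d_max` or exponential `exp(−2.99 d/d_max)`, both
exactly zero beyond d_max), the influence at a cell is the decay weight of
the **nearest** source cell, computed with an exact Euclidean distance
transform scaled to km. Degradation is

    D_x = Σ_r (ω_r / Σ ω) · i_r(x) · β_x · S_{j(x),r},  clipped to [0, 1].

*Why nearest-source?* The textbook degradation sum is over all source
cells, but published point validations behave as screened threats: a
farmland cell far from construction scores exactly H = 0.3, which requires
the influence to vanish when no source is in range and to saturate at the
closest source otherwise. Nearest-source (equivalently, max over sources of
i, with binary source intensity) reproduces that behaviour and makes D
independent of source-patch size; it is also what the brute-force oracle in
the test suite evaluates. A `mean` aggregation (mean decay weight over all
sources within d_max, via FFT convolution) is available through
`HabitatConfig(aggregation="mean")` for sensitivity analysis; it is always
≤ the nearest-source value.

Threat intensity r_y is binary (a cell either is or is not a source);
source-intensity rasters, habitat rarity and route-based decay are not
implemented.

### Quality and grading

    Q_x = H_{j(x)} · (1 − D_x² / (D_x² + k²))

* `k` (half-saturation): the degradation level at which quality halves.
  Not fixed by the published parameter tables this package defaults to;
  we use the conventional default k = 0.5. Every analytic point check is
  insensitive to k (each probe has D = 0 or H = 0).
* `β` (accessibility): default 1 everywhere; a raster may be supplied.
* Default threat table: farmland (d_max 1 km, ω 0.4, linear), construction
  land (d_max 10 km, ω 1.0, exponential). Default suitabilities:
  farmland 0.3, forest 1.0, shrub 0.9, grass 0.7, water 0.7,
  construction 0, barren 0.2, with the matching sensitivity matrix.

Grades use lower-inclusive intervals at (0.298, 0.698, 0.984): [0, .298)
Low, [.298, .698) Medium, [.698, .984) Good, [.984, 1] Excellent. The
conventional table writes the top grade as `1 > Q ≥ 0.984`, which literally
leaves Q = 1 ungraded; we include Q = 1 in Excellent. Alternative cut
points can be derived from the data with `jenks_breaks`, an exact
O(k·n²) Fisher dynamic programme (subsample large rasters first); ties and
optimality are deterministic for a fixed sample. Landscape means of Q and D
are unweighted means over all valid cells, all classes included.

## Markov demand

`P_ij = S_ij / Σ_j S_ij`; a class with zero first-epoch area receives an
identity row with a warning. One Markov step spans the calibration period
(14 years by default), so an equally long horizon is `steps=1`; no
annualisation (matrix roots) is attempted. Scenario presets multiply named
off-diagonal entries — EP: farmland→{forest, shrub, grass, water} ×1.5;
forest→all but water ×0.4; shrub→all but water/forest ×0.6; grass→all but
water/shrub/forest ×0.6; water→all but shrub/forest/grass ×0.6 ("reduced
by 60%" read as ×0.4, "increased by 50%" as ×1.5) — then restore row sums
by resetting the diagonal to 1 − Σ(off-diagonal), falling back to
proportional rescaling of the off-diagonals when the boosted row exceeds 1.
By construction the EP preset never raises forest→farmland and never
lowers farmland→forest.

## Expansion modelling and CA allocation

Positives for a class are all cells that newly converted to it between the
two dates; negatives are a seeded uniform background sample (default 1:1).
Features come from the driver stack, categorical layers one-hot encoded,
continuous layers raw (tree ensembles are scale-invariant). A seeded
scikit-learn random forest (50 trees by default) supplies the probability
surface and driver importances (one-hot columns folded back onto their
driver, normalised to sum 1). Classes with fewer than 10 expansion cells
are skipped.

The allocator works in integer cells; km² demand is rounded by largest
remainder so targets sum exactly to the valid-cell count. Per iteration,
classes with unmet demand (largest deficit first) score candidate cells as

    score = P_dev × (neighbourhood fraction × weight + u·seed_fraction) × gate

where u ~ U(0,1) is drawn from the seeded generator (so patches can
nucleate away from existing ones), the neighbourhood fraction is the class
share of the (2r+1)² window (nodata excluded, edge windows truncated), and
the gate is the conversion-cost entry for the donor→target pair. Only cells
of *donor* classes — classes currently above their own target — are
candidates, which prevents oscillation; cells above a global threshold
convert, best first, up to the deficit. If an iteration converts nothing
the threshold decays multiplicatively (default ×0.8 from 0.9). Cells of
protected classes (forest, shrub, grass, water) inside the restricted mask
are frozen, and an assertion verifies none changed. Termination: all
classes within `demand_tolerance`, or `max_iterations` (200); unmet demand
is returned as a per-class residual with `converged=False`, not raised.
A growing class without a trained probability surface falls back to a
neutral (all-ones) surface with a warning.

This is a deliberately simplified multi-seed CA: scheduling constants and
patch-size distributions of released desktop simulators are not replicated,
and numerical parity with them is not a contract — the behavioural
invariants (conservation of cells, mask inviolability, demand satisfaction
on feasible inputs, determinism under a fixed seed, preference for
high-probability cells) are.

## Validation metrics

Overall accuracy is trace/total of the confusion matrix; Kappa is
`(OA − p_e)/(1 − p_e)` with marginal chance agreement p_e, undefined
(NaN, warned) when p_e = 1. The Figure of Merit follows the standard
four-component definition: over jointly valid cells,
`FOM = B/(A + B + C + D)` with A = observed change simulated as
persistence, B = correctly simulated change, C = change simulated to the
wrong class, D = false-alarm change. Per-class producer/user accuracies and
quantity/allocation disagreement decompositions are out of scope.

## Synthetic landscapes

The generator produces the structure the pipeline assumes: ~90% forest
with farmland at its low-elevation edges, small water / construction /
shrub / grass / barren fractions, smooth correlated driver fields and a
contiguous restricted mask over the eroded forest core. Elevation is
spectrally smoothed seeded noise (correlation length = `patch_scale`,
default 8 cells) scaled to 0–1800 m; classes are assigned by quantiles of
an elevation-correlated field ordered water → construction → farmland →
barren → forest → shrub → grass from lowlands upward, so realized
fractions match the spec to within quantile granularity. Drivers include
slope/aspect (from gradients), Euclidean distances to random linear road /
rail features and to water, population and GDP declining exponentially with
elevation, temperature with a −6 °C/km lapse, smooth precipitation, and a
categorical soil layer. Change between epochs is rule-based — exactly
`n_cells` per (from, to) rule, optionally biased toward cells adjacent to
the destination class and low ground — so every transition count is known
by construction.

What this does **not** emulate: hydrologically consistent terrain, road
networks with topology, autocorrelated class boundaries matching any real
landscape, multi-date driver dynamics, or classification noise. A green
test therefore establishes the *mechanics* (accounting identities, model
equations, allocator contracts) — not predictive skill on real rasters,
which depends on data this package does not ship.

## Numerical notes

* Distances are centre-to-centre Euclidean via `scipy.ndimage.distance_transform_edt`
  (exact EDT), scaled by cell size; decay weights are clamped to 0 beyond d_max.
* Degradation and quality are float64; Q/D rasters are written float32 with
  NaN nodata, categorical rasters int32 with a tagged nodata code.
* Transition probabilities tolerate 1e-9 row-sum error; demand projection
  conserves total area to better than 1e-6 km² on realistic magnitudes.
* The GeoTIFF layer stores pixel scale, top-left tiepoint, a free-text CRS
  label and a GDAL-style nodata tag; it does not interpret projections.
  All inputs must share a grid; mismatch beyond 1e-6 of a cell raises.
* The Jenks oracle and the degradation brute force in the test suite are
  independent re-implementations (exhaustive partition search; all-pairs
  double loop) used only as references.

## Known limitations

* The trajectory encoding assumes ≤ 9 classes.
* The CA treats demand as a hard cell-count target; fractional-cell demand
  below half a cell is unreachable by construction (largest-remainder
  rounding), and competing classes are resolved greedily by deficit size.
* Threat sources are binary; partial-intensity threats would need a raster
  r_y, which the data model does not carry.
* `jenks_breaks` is quadratic in sample size; intended for samples ≤ ~5000.
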