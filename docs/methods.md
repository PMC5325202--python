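# Methods

`harvestrange` reimplements, as a tested pipeline, an analysis of how
boreal woodland caribou (*Rangifer tarandus caribou*) spatial behaviour
relates to forest-harvest landscapes that changed over two decades of
management. This note documents the models and procedures, their
assumptions, the parameters that matter, and what the synthetic data do
and do not demonstrate.

## Study design the pipeline assumes

Telemetry comes from two study regions (a western and an eastern
landscape that differ in range size and fidelity behaviour) and two
collar eras: a sparse ARGOS era (~1 location/day, graded by location
class) covering roughly 1995–2001, before a caribou-habitat management
policy, and a dense GPS era (a fix every 5 h, ~30 m error) covering
2009–2013, after it. The four region × period strata ("region-period
classes") are the `Group` factor in every model. All coordinates must be
planar meters in one projected CRS; every distance and area is Euclidean.

The biological year runs May 1 – April 30, anchored to calving onset.
Seasons: Winter Nov 16 – Feb 15, Spring Feb 16 – Apr 30, Summer May 1 –
Sep 15, Fall Sep 16 – Nov 15. (A year "ending April 31" does not exist;
April 30 is used.)

## Telemetry screening

ARGOS fixes keep location classes 3/2/1 only. Aberrant locations are
removed by a symmetric neighbour-speed screen: an interior fix whose
implied straight-line speed to **both** temporal neighbours exceeds
`max_speed_km_day` (default 50 km/day, configurable — the threshold is a
screening choice, not an estimate) is dropped; the screen iterates to a
fixed point so it is idempotent. Track endpoints are never dropped: a
single fast segment cannot identify which of its two fixes is wrong.
A run of two adjacent outliers straddled by good fixes can escape the
screen — a known limitation shared by neighbour-based filters. GPS fixes
pass untouched.

## Harvest landscape metrics

Annual harvest-block polygon layers (1991–2011) are unioned into 5-year
sliding windows (the window labelled 1995 is 1991–1995), matching 5-year
forest-management operating plans. Each window is rasterized by
cell-center containment and summarised by:

* **total class area** (km²),
* **mean patch size** (ha) with 8-neighbour patch connectivity,
* **Clumpiness Index (CLUMPY)** from rook like-adjacency proportions.
  With P the class proportion and G the like-adjacency fraction after
  subtracting the minimum attainable patch perimeter for the class's
  cell count (landscape-border faces excluded),
  CLUMPY = (G−P)/P when G<P and P<0.5, else (G−P)/(1−P). A solid block
  scores 1, a checkerboard at p=0.5 scores −1, and a spatially random
  map scores ≈ 0.

Distance-to-harvest rasters hold the exact Euclidean distance (meters,
cell center to cell center, `scipy.ndimage.distance_transform_edt`) to
the nearest harvest cell. The protocol value for distance rasters is a
25 m cell; the cell size is a parameter because metric values are
insensitive to it well below the block scale, and scaled-down runs use
100–150 m cells (the methods' own choice of problem size; see
"Problem sizes" below). Windows at the start of the series (before five
annual layers exist) are computed on the truncated window and flagged.

Datasets that record only per-year harvested areas (no polygons) can be
summarised with the same sliding windows via `sliding_window_totals`;
overlap between years cannot be deduplicated there, so window totals are
sums, not unions.

## Home ranges

* **MCP100** — convex hull of all locations (errors on <3 or collinear
  points).
* **KDE90** — bivariate Gaussian product-kernel utilization distribution
  with the reference bandwidth h_ref = σ·n^(−1/6),
  σ = sqrt((var_x+var_y)/2) (sample variances, n−1). The 90% range is
  the smallest superlevel set of grid cells holding 90% of UD mass; its
  area is the summed cell area. The grid is 200×200 cells spanning the
  point extent plus three bandwidths (both configurable); doubling the
  resolution moves the area by <2%. Annual ranges require ≥50 locations
  per animal per biological year — the sample size at which kernel range
  estimates stabilise — and are refused below it.
* **KDE90_bootstrap** — for dense GPS years, the kernel range of m = 65
  randomly selected locations (without replacement; a with-replacement
  flag exists), bandwidth recomputed per draw, averaged over 1000 draws
  (both configurable). This counteracts the incomparability of range
  estimates between ~300-fix ARGOS years and ~1700-fix GPS years. The
  era rule is automatic in the pipeline: early-period animal-years get
  the direct KDE90, late-period animal-years the bootstrap.

The KDE implementation exploits separability: the product kernel density
on a rectangular grid is a single matrix product of per-axis kernel
matrices, so a 65-point fit on a 100×100 grid costs one small GEMM.

## Proximity-to-harvest index

For each **summer** fix, observed distance = vector (point-to-polygon)
Euclidean distance to the nearest block cut within the preceding decade
(window (year−10, year], configurable; 0 inside a block). Expected
distance = mean of the distance raster over the cells of a reference
range:

* population scale — the 100% MCP of all class locations buffered
  outward by 7.5 km;
* annual scale — the animal-year's 90% kernel polygon.

The index is observed/expected per fix (a ratio-of-means summary is
available as a flag); class summaries are mean ± SE. Under uniform space
use within the range the mean index is 1 by construction — the
calibration tests verify 1 ± 0.05 with 10⁴ uniform fixes. The distance
field for each year is built on a grid covering the ranges **and** the
year's eligible harvest, so expectation and observation see the same
harvest, including blocks beyond the range edge. Fixes with no eligible
harvest in their decade, or in ranges without raster cells, are skipped
and logged.

## Summer fidelity index

Locations on the same calendar day in consecutive-year summers are
paired (day-of-year matching; for multi-fix days the fix nearest local
noon represents the day — deterministic and robust to the ARGOS-daily vs
GPS-subdaily schedules). An animal-summer qualifies only with ≥10 fixes
and at least one fix in every summer month. The animal's paired mean
pools distances over all its consecutive-year pairs. The class null is
the mean distance over all possible pairs of summer locations pooled
across the class's animals — per summer year first, then averaged across
years (fixed pooling order, so years with different fix counts weigh
equally; beyond 6000 fixes in a year the exact O(n²) mean is computed on
a logged random subsample). Fidelity index = null / paired; >1 indicates
fidelity.

Because the index is a mean of ratios, Jensen's inequality biases its
class mean above 1 when every animal is tightly localized around an
independently drawn center (each animal's paired mean is then a single
noisy draw, and E[1/X] > 1/E[X]; ≈1.3 in our simulations). The index
calibrates to 1 under movement with no fidelity mechanism *and*
non-trivial within-summer spread — wandering, unbiased-walk summers —
which is the null the calibration tests simulate. Interpreting small
elevations of the index therefore requires care when animals are highly
localized; large values (≫1) are unambiguous.

## Harvest-exposure covariates

All covariates use harvest under 15 years of age relative to the row's
biological year (window (year−15, year]), and are percentages in
[0, 100]:

* **CutinHR** — percent of the animal-year's 90% kernel range in harvest.
* **CutHRBuffer** — percent of the buffer *ring* (buffer minus range)
  around the kernel range in harvest. Ring width is the square root of
  the regional mean annual 100% MCP area: 21 km (west), 37 km (east) by
  default, recomputable from data by flag. The ring (not the filled
  buffer) is measured because the covariate describes the surroundings
  of the range, not the range itself.
* **CutBuffer** — percent harvest within the 7.5 km buffer around the
  block nearest the fix (missing when no eligible harvest exists). The
  value depends only on the nearest block's identity, so the pipeline
  caches it per (year, block) behind an STRtree query.
* **CutPoint** — mean percent harvest within a disc of radius
  sqrt(mean MCP area / π) — 12 km (west), 21 km (east) — around each of
  the animal's fidelity fixes.

## Model selection

Each response is fitted over a small candidate set of fixed-effect
structures (always including the Null model) built from `Group` and the
covariates above; the sets mirror the study's reported top-model tables
per response. Responses with repeated measures per animal (home-range
area, both proximity indices) are linear mixed models with a random
intercept per individual, fitted by **maximum likelihood** so AICc is
comparable across fixed-effect structures; fidelity (one value per
animal) is OLS. A square-root response transform is a per-response
configuration flag (defaults: on for home-range area and fidelity),
never an automatic normality test — reproducibility over hidden
heuristics.

AICc = −2logL + 2k + 2k(k+1)/(n−k−1), with k counting fixed effects plus
variance components (random-intercept and residual variances for LMMs,
residual variance for OLS). Candidates are ranked by AICc; Akaike
weights w_i ∝ exp(−Δ_i/2). Models with Δ < 2 are averaged with
renormalised weights (conditional/natural averaging: a coefficient is
averaged over the subset models containing it); variable importance sums
full-set weights over candidates containing the variable. When the best
model keeps `Group`, all pairwise region-period contrasts are tested
with single-step (max-|z|) adjustment: adjusted p-values and
simultaneous 95% CIs come from rectangle probabilities of the contrasts'
joint normal distribution, the same family of adjustment as multcomp's
`glht` single-step method.

Numerical details: mixed fits try the bfgs, lbfgs and cg optimizers in
order and accept the first converged, finite, interior fit. When the
random-intercept variance collapses to the zero boundary (where some
optimizers return singular Hessians or infinite likelihoods), the fit is
replaced by OLS, whose ML likelihood and fixed effects equal the
boundary LMM exactly; k still counts the variance parameter so AICc
comparisons stay consistent. Genuinely non-convergent candidates are
excluded with a warning. Bespoke residual correlation/variance
structures (of the kind `nlme` offers) are not reproduced; the
random-intercept structure is the documented default.

## Synthetic-data generator

The generator is first-class, tested code that emulates the study
design:

* **Harvest**: per year, rectangular blocks (lognormal area, random
  aspect and rotation) placed by a clustered parent–offspring process —
  κ parent points per year, offspring scattered around them — until the
  realized union area is within 10% of the year's target. Fewer parents
  (smaller κ) means more aggregated harvest (higher CLUMPY). Default
  annual targets rise linearly to a 2002 peak (70 km²/yr west,
  110 km²/yr east) and then decline geometrically (×0.76/yr west,
  ×0.70/yr east), producing ~80%/~90% declines in 5-year window totals
  from the 2002 window to 2011 — the scale of decline the study region
  experienced.
* **Movement**: a biased correlated random walk. Step length is
  half-normal with daily scale σ_step; heading mixes the previous
  heading with the bearing to the animal's seasonal center (attraction
  s, converted per time step as 1−(1−s)^dt). Each biological year the
  center is redrawn with persistence φ (center_y = φ·center_{y−1} +
  (1−φ)·fresh; φ=1 identical, φ=0 independent) and the animal relocates
  to it with 5 km noise — seasonal migration to the summering area.
  φ and s jointly control site fidelity; σ_step controls range size.
* **Harvest avoidance**: steps that would *enter* the neighbourhood
  (default 1 km) of blocks cut in the past decade are accepted with
  probability exp(−a) (up to 10 proposals, else the animal stays); an
  animal already inside moves freely, so it can always leave. The same
  acceptance penalty applies to seasonal-center selection, representing
  summer-range selection away from cutblocks — without it, animals whose
  centers land in harvest would mask the step-level mechanism entirely.
* **Observation**: ARGOS fixes get a location-class mixture (including
  classes 0/A/B/Z that the screen must remove) and class-dependent
  Gaussian position error (250/500/1500 m for classes 3/2/1, larger for
  the rest); GPS fixes get 30 m error on a 5 h schedule.

Randomness: one root seed; every animal gets a spawned stream, and
within an animal each biological year derives its own center and
movement streams with fixed-size draw blocks per step. Consequently a
single seed fixes the whole bundle bit-for-bit (`make_study` writes a
manifest with SHA-256 checksums), and parameter sweeps under a fixed
seed vary smoothly with the parameter.

Default movement parameters (west: σ_step 6.5 km/day, s 0.45, φ 0.95,
a 2; east: σ_step 6 km/day, s 0.30, φ 0.50, a 0) were chosen so that
simulated annual KDE90 ranges land near field-realistic magnitudes
(west ≈ 2000, east ≈ 7000 km²) and the west≫east fidelity contrast is
expressed (index ≈ 2.5 vs ≈ 1.1). Animal counts default to the study's
design (34/30 early, 60/60 late).

**What the generator does not emulate**: within-year seasonal range
shifts (one attraction center serves the whole biological year, so
simulated fidelity indices are more modest than field values driven by
tight calving-site fidelity); collar dropout and irregular duty cycles;
terrain, water, roads or any habitat structure beyond harvest; predator
or conspecific effects; demographic turnover. Passing tests show the
*estimators* respond correctly to their generating parameters — they do
not validate the movement model against real caribou.

## Problem sizes

Full-design simulation (~200 animals over two eras) is supported but
slow on one core; the test suite and the acceptance script run
scaled-down studies as their own choice of problem size: 2–5 animals per
class, 3 ARGOS years and 2–3 GPS years, 100–150 m raster cells, 20–100
bootstrap draws, and 120-cell UD grids. Every reported quantity carries
the n actually used. Monotonicity checks use dedicated small worlds
(one region, fixed harvest) with 6–10 animals per parameter level.

## Known limitations

* Expected distances use cell-center containment; very narrow range
  slivers can contain no cell centers and are skipped (logged).
* The all-pairs fidelity null subsamples above 6000 fixes per year
  (exact below); class nulls from very few animals are dominated by
  within-animal pairs and should not be interpreted.
* CLUMPY's min-perimeter correction follows the FRAGSTATS v4 class-level
  definition; other FRAGSTATS metrics are out of scope.
* AICc parameter counts treat boundary variance components as full
  parameters (conservative).
* No CRS handling: inputs must already be projected planar meters.
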