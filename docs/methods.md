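# Methods

## Estimation model

The core quantity is per-pixel standing-dead biomass accumulated over a
multi-year die-off, estimated by fusing two data streams:

* **survey polygons** — areas of observed mortality delineated from
  aircraft, each with a (possibly fractional) dead-tree count for one
  survey year;
* **pre-die-off structure rasters** — live trees/ha (TPH), live
  aboveground biomass/ha (BPH, bone-dry tons) and live stem volume/ha
  (VPH, m³) on a 30-m grid (0.09 ha/pixel), in two tree-size variants:
  trees ≥ 25 cm DBH and trees ≥ 2.5 cm DBH.

Each polygon's count is split across its forested pixels proportionally to
TPH and capped at the pixel's live-tree stock; biomass follows by the
pixel's mean live-tree biomass BPH/TPH; cumulative totals are capped at the
pixel's live biomass. Assumptions inherited from the method: every tree in
a polygon is equally likely to die and be detected, regardless of size;
dead wood density does not decay over the analysis window; all estimates
refer to the pre-die-off structure baseline.

Aircraft observers cannot see small stems, so the ≥ 25 cm variant is the
detection-matched **upper bound** on biomass (fewer but heavier candidate
trees per count) and the ≥ 2.5 cm variant the **lower bound**. Both runs
consume identical survey counts.

Deliberate procedural choices where the method's description is silent:

* **No redistribution.** Dead trees truncated by a pixel cap are not
  reallocated to other pixels; the shortfall is logged per polygon. No
  redistribution rule exists that would not invent information.
* **Overlapping polygons** (within or across years) are allocated
  independently against the same pristine baseline; only the cumulative
  live-biomass cap reconciles them. Per-year layers are kept uncorrected
  because the cumulative correction cannot be attributed to years.
* **Rasterization rule:** a pixel belongs to a polygon when its center
  lies inside or on the boundary. The per-polygon TPH denominator uses
  only member pixels with TPH > 0.
* **Fractional trees** are allowed throughout; proportional division of
  survey counts is inherently fractional.

## Feasibility screening

Four sequential filters, in fixed order (attribution of removed biomass
depends on order): spatial isolation, wilderness/National Park, tree size,
dead-tree density.

**Spatial isolation.** DBSCAN over centers of pixels with positive
cumulative dead biomass, Euclidean metric, minimum cluster size 112 pixels
(≈ 10 ha). A point's ε-neighborhood includes itself; with that convention,
on a fully occupied 30-m lattice 113 centers fall within 180 m of a center
but only 109 within 179 m, so **no cluster can form for ε < 180 m** — a
property asserted in the tests. The radius ε is chosen by sweeping
180–400 m in 20-m steps (configurable) and taking the point of maximum
discrete (Menger) curvature of the min-max-normalized trade-off curve
between biomass removed as noise and mean cluster standard distance
(SD = √(var x + var y) about the cluster centroid). Ties, and the
zero-curvature degenerate case, resolve toward the smallest interior ε
because smaller ε yields more compact clusters. Clustering runs on the
upper-bound grid and the resulting noise mask is applied to both variants,
so both bounds describe one spatial footprint.

**Wilderness/National Park** pixels (center containment) are removed:
mechanical harvest is excluded there.

**Tree size and density.** Mean volume per tree VPT = VPH/TPH; pixels with
VPT ≥ 11.32 m³ (facility chipping in-feed limit; boundary inclusive — a
mean tree at the limit cannot be chipped) or cumulative dead-tree density
strictly below 2.5/ha are removed. VPT is taken from the detection-matched
(≥ 25 cm) variant, falling back to the all-tree variant where the
large-tree layer is empty, and the resulting drop mask is shared by both
bounds (same one-footprint rationale as for clustering). Pixels with
TPH = 0 have undefined VPT, carry no dead biomass, and never reach a
threshold comparison.

## Cost classification

Feasible pixels are labeled along four independent dimensions; each
dimension partitions the feasible total exactly (asserted):

| dimension | classes | boundary convention |
|---|---|---|
| tree size | on-site chippable ≤ 2.26 m³ / facility-only | 2.26 → on-site (the published class definitions overlap at the boundary; this choice is documented, not derived) |
| slope | ground < 30 % / transitional 30–40 % / cable-heli > 40 % | 30 → transitional, 40 → cable-heli |
| road access | near ≤ 2000 m / far | 2000 → near |
| hazard zone | tier 1, tier 2 (may overlap), county | center containment |

Slope is Horn's 3×3 finite-difference gradient of the DEM, in percent,
with edge-replicated neighborhoods (exact on inclined planes away from the
outermost ring). Road distance is straight-line to the nearest road line;
an empty road network classifies every pixel as far. The **cost-effective**
subset is VPT ≤ 2.26 AND slope < 40 (strict) AND road ≤ 2000 m. Summary
tables report per-criterion splits, hazard-tier totals (tiers may overlap,
so tier rows can exceed their union), and per-county shares; percentages
are computed from unrounded totals and rounded only at serialization
(2 decimals for county shares, 1 decimal for TWh/Tg in reports).

## Energy and carbon

Linear conversions with cited industry constants, not derived from first
principles: 1 BDT/MWh (conventional boiler), 4.7 BDT/MWh (small-scale
gasifier), plant output MW × 8760 h × capacity factor (default 0.80), with
an explicit annual-generation override for reproducing published round
figures (e.g. 0.4 TWh/yr for a 50 MW target, where the arithmetic gives
0.3504). Supply-years round to the nearest integer, half away from zero.
Carbon: 907.18474 kg/BDT (2000 lb) × carbon fraction 0.47. The 0.47
default reproduces the published Tg C endpoints at 1-decimal rounding in
four of five cases; the fifth (95.1 million BDT) computes to 40.5 against
a published 40.6 — a known 0.1 discrepancy, left visible rather than
tuned away. The fraction is configurable.

## Validation

Per survey polygon, the pipeline's dead-biomass sum (years within the
comparison window, live-biomass cap applied per pixel) is compared with an
independent biomass-loss raster summed over the same pixels, *excluding*
pixels where the reference shows net gain. Polygons are excluded when
smaller than 2700 m² (three 30-m pixels — the published exclusion states
"2700 m³", presumed a unit slip for area since it is glossed as three
pixels; the parameter is named `min_polygon_area_m2`), when they fail the
feasibility screens at polygon level (mean VPT, dead density, no clustered
pixel), or when either side is non-positive (reported separately). The
agreement statistic is RMSE of ln(estimate) − ln(reference); **natural**
logs are used — the published account says only "log-transformed", and
log-RMSE is base-dependent, so this choice is flagged prominently.

## Synthetic landscape generator

The generator's defaults define the study conditions for all tests:

* 150 × 150 pixels at 30 m (4.5 × 4.5 km), 70 % forest;
* spatially autocorrelated fields as Gaussian-smoothed white noise
  (σ = 6 pixels), mapped through a logistic into stated ranges — a
  deliberately dependency-light construction rather than a named
  geostatistical simulator;
* all-tree TPH around 300/ha; large-tree fraction 0.25–0.55; all-tree mean
  tree biomass 0.08–0.45 BDT and volume 0.2–4 m³, with the large-tree
  subset boosted by 1 + (1/f − 1)·g (g ∈ (0.3, 0.9)) so that, by
  construction, subset totals stay below population totals while subset
  *mean* trees are heavier/bigger — the ordering a size-thresholded
  inventory must obey. The volume range reaches high enough that a small
  tail of old-growth-like pixels exceeds the 11.32 m³ screen;
* six survey years, 8 blob polygons per year (buffered random walks —
  always valid single-part polygons), per-polygon mortality fractions
  0.02–0.35 of live trees (well above background mortality, below stand
  replacement; the low end produces sub-2.5/ha dead densities so the
  density screen is exercised);
* **proportional mode**: a polygon's count kills exactly the drawn
  fraction of every member pixel's trees, so proportional allocation
  recovers the truth to machine precision and no within-polygon cap binds
  (at fraction 1.0 every pixel sits exactly at its cap); **size-biased
  mode** skews deaths toward heavy-tree pixels to exercise estimator error;
* **tiled placement** confines each polygon to its own tile so polygons
  never overlap — used where an experiment needs the per-pixel-year cap to
  hold as a raster invariant or needs unmixed noise factors;
* DEM flat, inclined plane (known slope everywhere), or random smooth
  surface scaled to a 25 % RMS slope so all three slope classes occur;
  4 wavy roads; wilderness/tier-1/tier-2 blob covers of 15/10/35 % of the
  extent; a 2 × 2 rectangular county partition;
* reference loss raster = per-polygon truth × one lognormal factor per
  polygon (independent change maps err coherently over a disturbance
  patch; per-polygon noise also makes polygon-level log-RMSE converge to
  the injected σ, which iid per-pixel noise would not), with optional
  injected net-gain pixels;
* one master seed spawns named substreams (structure, mortality, DEM,
  roads, zones, reference) so components regenerate independently; equal
  seeds give bit-identical bundles.

What the generator does **not** emulate: species composition and real
allometry, beetle-pressure dynamics, decay, survey-boundary digitization
error, spatial correlation between mortality severity and terrain. Passing
tests therefore demonstrate the correctness of the accounting, filtering
and statistics on internally consistent inputs — not the field accuracy of
aerial counts or imputed structure maps.

## Problem sizes and numerics

Test and acceptance runs use the 150×150 default landscape (~50 polygons),
fifty 40×40 bundles for the conservation/cap sweep, and a 420×420 tiled
landscape for the 500-polygon noise-recovery experiment; these sizes were
chosen as the smallest at which every regime (caps binding and not,
clusters forming and not, all exclusion reasons) actually occurs.
Floating-point ties at class boundaries follow the conventions above;
comparisons in tests use absolute tolerances scaled by the field maximum
(1e−10 for recovery). Degenerate inputs are defined, not special-cased:
zero-forest polygons allocate nothing and log a warning; an empty road
network yields infinite distances; a clusterless sweep point records a
missing compactness value; an all-linear trade-off curve falls back to the
smallest interior ε with a warning.

## Known limitations

* ε selection reproduces the published *procedure*; the published
  statewide value (ε = 220 m) depends on the real statewide data and is
  not reproducible from synthetic inputs.
* The published statewide log-RMSE values (0.53/0.74) likewise require
  the real survey/structure/reference stack; only the statistic's
  noise-recovery behaviour is verifiable here.
* The published gasifier TWh ranges are inconsistent with dividing by the
  stated 4.7 BDT/MWh; the package applies its stated factor and does not
  attempt to match those two ranges.
* No hauling-distance or dollar-cost model, no decay adjustment, no
  reprojection/resampling (inputs must share one metric grid).
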