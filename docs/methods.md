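# Methods

This note documents the models and procedures `forestinv` implements, the
parameters that matter, the numerical choices made where the published
descriptions of these techniques leave room, and what the synthetic-stand
tests do and do not demonstrate about real data.

## Ground classification (cloth simulation)

The cloud is inverted in z and a grid of cloth particles (spacing
`cloth_resolution`, default 0.20 m) is dropped onto it. Each iteration a
movable particle takes a Verlet gravity step, then `rigidness`-dependent
spring passes (low/medium/high → 1/2/3) pull it halfway toward the mean
of its four neighbors; a particle freezes when it reaches the height
control value of its node (the highest inverted point binned there;
empty nodes inherit the nearest occupied node's value). Points within
`class_threshold` (default 0.20 m) of the settled cloth are ground.

Numerical choices:

- The per-step displacement is `G·time_step²` with a normalized gravity
  constant G = 0.2, i.e. ~8 cm per iteration at the stock 0.65 time
  step. Published cloth-filter implementations differ in their time-step
  semantics; a small step is essential here, because a multi-meter step
  lets the cloth punch through one-node canopy "wells" (grid cells whose
  only points are canopy) before the springs can bridge them. With 500
  iterations the cloth can still descend ~40 m, far more than any stand
  relief this tool targets.
- Spring passes reset the Verlet velocity, so gravity does not accumulate
  momentum across iterations and the equilibrium sag over unsupported
  nodes stays at centimeter scale.
- The cloth grid extends one `cloth_resolution` beyond the cloud's
  bounding box; classification compares each point to the bilinearly
  interpolated cloth. No post-hoc slope smoothing is applied.
- The grid is anchored to the cloud's own bounding box, which makes the
  classification exactly invariant to rigid xy-translation and to adding
  a constant to z.

## Height normalization

Each point's elevation becomes z − ĝ(x,y), where ĝ is the
inverse-distance-weighted (power 2) mean of the k = 10 nearest ground
points within 0.50 m. A point exactly on a ground point takes that
ground elevation, so ground points normalize to exactly 0. Points with
no ground neighbor in the radius fall back to the single nearest ground
point (with a warning) rather than being dropped: silently shrinking the
cloud would bias every downstream stage.

## Canopy height model and tree detection

The CHM assigns each 10 cm cell the maximum normalized height of its
points; cells are half-open intervals anchored at the cloud's lower-left
corner, points on the outer edge joining the last cell, and empty cells
are nodata. No pit-filling or smoothing is applied.

A pixel of height h is a tree top iff it is ≥ every non-nodata pixel
whose center lies within the Euclidean radius `0.1·h` (floored at one
cell so short trees have a defined window) **and** strictly above at
least one of them. The strictness rule excludes constant fields; an
isolated pixel with no non-nodata neighbor in its window still counts
(a lone tree in an empty raster is a tree). On equal-height plateaus
only the first pixel in row-major order is kept. Detected trees keep
pixel-center coordinates — no sub-pixel apex refinement — and only trees
above 1.37 m (breast height) are returned.

## Stem extraction

Five steps on the normalized cloud:

1. **Slice** to 0.1–4.0 m, the zone where stems dominate.
2. **Map stems**: points in the 1.32–1.42 m band are binned to a 2.5 cm
   occupancy grid; a Hough circle search over radii 2.5 cm…50 cm (2.5 cm
   steps) votes at candidate centers. A peak's score is its votes
   divided by the circle circumference in cells, so a fully sampled
   circle scores ≈1 regardless of radius; peaks below `map_min_density`
   (default 0.001) are dropped, and peaks within 1 m merge to the
   strongest. The density thresholds are interpreted as these fractional
   vote densities; an absolute per-area reading of "0.001 points per
   square meter" is not workable for clouds at hundreds to thousands of
   points per square meter.
3. **Attribute tree IDs**: points within 0.5 m of a candidate center get
   its ID; points in range of several centers go to the nearest.
4. **Classify stem points**: per tree and per 0.5 m vertical segment,
   the Hough search (max diameter 1.5 m, min density 0.1) proposes a
   circle, refined by an algebraic (Kåsa) least-squares fit on points
   within 5 cm of the ring; points farther than 2.5 cm radial distance
   from the refined circle are rejected, survivors become stem points.
   Trees where no segment yields a circle drop out of the stem set.
5. **Fit DBH**: the stem points in the 0.1 m band centered at 1.37 m are
   flattened, binned to 1 cm occupied cells, and fit by RANSAC (500
   seeded iterations, 3-cell minimal samples via the circumscribed
   circle, 1.5 cm inlier tolerance) with a final Kåsa refit on the best
   consensus set. Reported: center, DBH = 2r in cm, inlier count, and
   radial RMSE. Fits with fewer than 3 occupied cells or diameters
   above 1 m are rejected.

The 2.5 cm accumulator and 1 cm DBH raster sit well below the smallest
stem of interest (8 cm); both grids anchor to the data's bounding box,
so the whole stage is translation-invariant. The Kåsa fit is the
standard linearized circle least squares; its known bias on short arcs
stays within ~0.3 cm at the 120° arcs the tests exercise.

## Allometry and matching

The height–DBH relation is the power function `DBH = a·Hᵇ` (cm, m), fit
by nonlinear least squares initialized from the log–log regression (the
log–log closed form is the fallback if the optimizer fails). The "90th
percentile bounds" are the 5th/95th percentiles of the additive
residuals DBH − a·Hᵇ, so the band brackets the central 90% of training
data. Quantile regression or multiplicative bands were plausible
alternatives; additive residual percentiles are the simplest
reproducible construction. No mixed-effects structure is used.

A regional inventory is first reduced to site-comparable plots: site
index within ±2 m (inclusive) and dominant-species basal-area share
strictly above 0.70.

Matching is greedy and one-to-one: all (stem, top) pairs within 4 m are
ranked by |extracted DBH − regional DBH(height)| and the globally
cheapest remaining pair is accepted repeatedly. Taking the global
minimum each round makes the result independent of input order; ties
break by distance, then stem id, then tree id. Stems with no top within
4 m are dropped. Matches outside the regional residual band are
discarded; the site model is refit on the survivors (≥3 required,
otherwise the regional model substitutes, loudly) and predicts DBH for
every unmatched tree, yielding a complete tree list.

Note one behavior inherent to allometric-cost matching: a grossly wrong
extracted DBH near a taller tree can occasionally pair with that taller
top (whose regional prediction resembles the wrong value) and then pass
the residual filter. The filter itself rejects essentially every ±20 cm
corruption of a correctly matched pair; what it cannot fix is a
mis-pairing upstream. This is visible in the stem-level corruption test,
which passes its ≥90% removal bound at n = 200 but not deterministically
at n = 5.

## Synthetic stands

The generator emulates the open-canopy conifer regime this method
requires; its defaults are the test conditions throughout:

- 50 trees on 50 m × 50 m, Poisson-disk placed at ≥3 m spacing, heights
  uniform on 5–20 m; DBH = 2.5·H^0.9 + N(0, 1 cm).
- Bare cylindrical stems (radius DBH/2) below 30% of tree height at 600
  points per meter of stem; narrow conical crowns above, radius 0.1·H
  clipped to [0.4, 2.0] m, sampled at 300 points/m³ with 70% of points
  on the lateral cone surface (what photogrammetry actually
  reconstructs) and a guaranteed apex point; ground at 1,000 points/m²
  on flat, sloped (15%), or rolling terrain. Total ≈1,100 points/m²,
  the lower end of published SfM stand densities.
- A regional inventory of plots whose height–DBH pairs follow the same
  power law with 3 cm residual sd, a configurable fraction constructed
  to survive the site-comparability filter.
- An occlusion mode restricts stem sampling to a 180° arc to exercise
  partial-arc circle fitting.

Everything is deterministic given the seed, and every point carries its
true class and tree id.

What passing these tests shows: the window rule, circle fits, filters,
matching, and model fits implement their definitions correctly, and the
pipeline recovers a stand whose geometry satisfies the method's own
assumptions (visible stems, non-interlocking crowns, ground visible
between trees). What it does not show: robustness to SfM reconstruction
noise, co-registration error, understory vegetation, interlocking or
irregular crowns, leaning or non-circular stems, or occlusion patterns
beyond the simple 180° arc — on real clouds, DBH extraction rates of
10–80% and filter removal of a large share of extracted DBHs are the
expected regime, which is exactly why the matching/filtering/modeling
half of the pipeline exists.

## Problem sizes and determinism

The shipped tests run stands of 10–15 trees at reduced ground density
(100–300 points/m²) for speed; the acceptance script and the end-to-end
acceptance test use the full 50-tree, ~2.9-million-point configuration.
All randomness (generator, RANSAC, experiments) flows from explicit
seeds; repeated runs are byte-identical. Translation invariance of the
raster-based stages holds exactly up to least-squares round-off
(~10⁻⁸ cm), which is the tolerance the invariance tests use.

## Known limitations

- LAS support covers uncompressed LAS 1.2 point formats 0–3; LAZ must be
  decompressed externally.
- The cloth filter omits post-processing slope smoothing; extremely
  steep terrain (>40°) with dense canopy may need a finer cloth or a
  higher rigidness than the defaults.
- Site index is treated as a caller-provided scalar; no base-age or
  species conversion is attempted.
- Crown segmentation is out of scope: tree tops are points, not crowns.
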