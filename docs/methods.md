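# Methods

This note documents the models implemented in `cliffscout`, the defaults
chosen where the design was genuinely open, and what the synthetic tests do
and do not demonstrate about real survey data.

## Raster model and slope

Rasters are regular square-celled grids in planar metres (projected,
UTM-like coordinates; no geodesy — adequate at the 10×10-km survey-square
scale).  Row 0 is the northernmost row; the origin is the outer corner of
the lower-left cell, matching the ESRI ASCII Grid convention used for all
raster I/O.  Cell ownership is half-open: a point on an interior shared
edge belongs to the cell with the larger row/col index, so every point maps
to exactly one cell.

Slope is Horn's 3×3 weighted finite difference, reported as a
**dimensionless gradient** (rise/run).  Studies in this area rarely state
the unit of their slope thresholds; gradient is assumed here because
occupied-cliff values in the 0.34–0.68 range read naturally as gradients
(0.34 ≈ 19°, 0.68 ≈ 34° — plausible for cliff bases smoothed by a 5-m DEM),
whereas as percent/100 they would be implausibly gentle, and degrees would
put every threshold under 1°.  The assumption is configurable simply by
supplying thresholds on whatever scale the slope raster uses.  The
operator is exact
for affine planes (slope(a·x + b·y + c) = √(a² + b²), tested to 1e-9) and
invariant under constant elevation shifts.  Edge cells and cells whose 3×3
window touches nodata are nodata: no data is invented at boundaries, which
is why synthetic nest sites are kept off the outermost cell ring.

## Cliff classification

Thresholds come from the slope values at occupied nesting cliffs, read from
each site's single containing cell (a 3×3 neighbourhood maximum is a
conceivable alternative; the point reading is the simplest faithful
choice).  Percentiles interpolate linearly between closest order statistics
(the common statistical-software default).  Classification uses `>=` so the
occupied cliff holding the sample minimum is itself captured by the *S*min
map; together with s_min ≤ s_25 ≤ s_50 this makes the three maps nested and
guarantees every *sampled occupied site* is cliff under *S*min.  Note that
producer's accuracy measured on independently sampled ground-truth cliff
cells can still fall below 100% for *S*min: truth cells that were not
occupied sites (e.g. the diluted edge cells of a scarp face) may be gentler
than the occupied minimum.

## Viewsheds

The sightline test is the classic exact profile test: the 3-D segment from
the observer's eye (ground elevation + eye height) to the target (ground
elevation + target height) is checked against the terrain at every crossing
with the grid lines through cell centres, interpolating terrain linearly
between the two adjacent centres along the crossed line, **plus** the
midpoint of every crossing interval — along a ray the bilinear surface
within one cell is quadratic and can bulge above its values at the
crossings, and the midpoint check removes almost all such misses (the test
suite verifies ≥ 99% cell agreement with a dense-ray oracle that samples
bilinear terrain every cell_size/10).  Remaining disagreements are grazing
ties and sub-interval bulges.  Nodata terrain is opaque; a target in the
observer's own cell is always visible; visibility is monotone in eye height
and in the observer set.

Defaults: eye height 2.5 m (a vehicle-mounted panoramic camera), target
height 0 m, unlimited radius (per-square viewsheds are reported without a
radius; the pipeline caps rays at 3.5 km purely to bound computation, a
distance at which the logistic identification probability is already
≈ 10⁻⁷).  Observer spacing defaults to one cell so no road cell is skipped;
the pipeline uses 100 m (two cells) as its own speed/fidelity trade-off.
Earth curvature, refraction and vegetation occlusion are out of scope: this
is *potential* visibility, as a GIS viewshed reports.

## Accuracy assessment

Ground truth is sampled stratified by survey square: each class's points
are apportioned by largest remainder (with equal quotas the extras go to
consecutive strata, the two classes' extras on disjoint strata, so
per-square totals differ by at most one — e.g. 100 points over 7 squares
gives 14–15 per square), then drawn uniformly without replacement within
stratum, deterministically given a seed.

All metrics derive from the 2×2 confusion matrix.  User's accuracy and
commission error carry a **convention switch**: the textbook (map-relative)
commission error is fp/(tp+fp), but published cliff-mapping tables in this
line of work pair user's accuracy 90 with commission 0.10 for counts
(tp, fn, fp, tn) = (49, 1, 5, 45) — consistent only with the
reference-relative form fp/(fp+tn).  Both are implemented and labelled;
reference-relative is the default.  Cohen's κ is the standard single-rater
two-category form; with balanced reference classes chance agreement is
exactly ½, so κ = 2·p₀ − 1, a closed form the tests exploit.

## Survey economics

The on-ground survey drives all drivable roads at 30 km h⁻¹ and 0.19 € km⁻¹
(fuel only); remote inspection costs screen time and no money.  Totals are
normalised per km² of surveyed (viewshed) area.  With f the coincident
fraction (remote viewshed / ground viewshed), per-km² time rates t_g, t_r
and ground money rate c_g:

    time_saved = f · V_g · (t_g − t_r)      pct_time = 100 · time_saved / (V_g · t_g)
    cost_saved = f · V_g · c_g              pct_cost = 100 · f   (remote money cost 0)

which satisfies the accounting identity: combined time = remote time on the
coincident area + ground time on the remainder = ground-only time −
time_saved.  Travel to/from squares is excluded (savings are conservative).
A remote method slower than the ground one yields a negative saving with a
warning flag, not an error.  Per-square savings are averaged
square-by-square (not pooled) when means are reported.  Paired comparisons
use the Wilcoxon signed-rank test (zero differences dropped, exact null for
n ≤ 25; identical samples return V = 0, p = 1 by convention) and the paired
t test.

## Detectability

Distances are exact point-to-segment Euclidean minima over covered
polylines (shapely).  Group comparisons are Welch t statistics computed
from means and standard errors, |m₁ − m₂| / √(se₁² + se₂²), reported both
unrounded and at the 2-decimal print precision; Welch–Satterthwaite df and
p-values are attached when group sizes are known.  The 2×2 χ² offers both
the Pearson and Yates-corrected forms.  Feature detection tables count, per
feature, field-flagged sites and remotely-confirmed sites, with the
detection rate over all field-flagged sites.

## Synthetic data: what it emulates, and what it does not

* **Terrain** — a smooth double-sinusoid base (default amplitude 40 m,
  wavelength 1.8 km; max base gradient ≈ 0.17) plus 12 finite linear scarps
  (heights 40–120 m over a 2-cell face at 50 m cells: face gradients
  0.4–1.2, well separated from the base), tapered along strike; face cells
  are the cliff truth class.  Scarp centres are stratified over the four
  landscape quadrants so every analysis square contains cliffs.
* **Roads** — a jittered lattice (spacing 1.6 km) split into ~1 km
  segments; 35% of lines are unpaved tracks (drivable, never
  imagery-covered).  Covered segments are accumulated in random order and
  the last one split at the exact residual, so the covered share of paved
  length hits the 0.49 target almost exactly.
* **Scarp–road setback** — scarp centres keep 500 m from covered roads
  (roads skirt cliff faces in real terrain).  This is the free geometry
  parameter calibrated once so that, with the identification model below,
  the identified-site distance distribution has its median near 800 m at
  the default road density; with sites uniformly placed relative to roads
  the nearest-distance density piles up at zero and no road spacing alone
  can push the identified median that high.
* **Nest sites** — 148 cells drawn without replacement from the truth mask
  (off the border ring); independent feature flags at prevalences 0.77
  (white spots), 0.59 (caves), 0.76 (vegetation); species occupancy drawn
  with shares 0.297 griffon-only / 0.608 Egyptian-only / 0.095 both.
* **Identification** — P = logistic((d₅₀ − d)/s) with d₅₀ = 1000 m,
  s = 150 m (an approximate 1-km identification limit), gated by visibility
  from covered roads.  Remote feature flags thin the field flags with
  per-feature probabilities 0.40 / 0.28 / 0.65, independent across
  features, conditional on identification.
* **Survey times** — per-square per-km² rates drawn from lognormals matched
  by moments to mean 0.91 (SD 0.21) min km⁻² remote and 3.97 (SD 2.94)
  min km⁻² ground; zero SD degenerates to the mean.

Every draw derives from one seed through independent substreams, so each
generator operation is reproducible regardless of call order.

**Problem sizes.** The default landscape is 8×8 km at 50 m cells (160×160);
the pipeline analyses four 4×4-km squares with observers every 100 m and a
3.5 km ray cap, which keeps a full end-to-end run under about a minute.
These are the package's own desk-scale study conditions: real 5-m DEMs over
7,000 km² are three orders of magnitude larger and were processed in a
commercial GIS in the motivating study.

**What passing tests show.** That the algorithms are correct (against
independent oracles), that the statistical machinery reproduces published
summary arithmetic exactly, and that the simulated observation process has
the qualitative structure of the field system (identified sites nearer
covered roads, Welch t ≫ 2; d₅₀ recoverable by ML refit within ±10% at
n = 1000).  They do not show that real viewshed coverages, per-square
costs, or detection rates equal the synthetic ones: those depend on real
road geometry, terrain and imagery that the generator only caricatures.
Field-scale coverage figures are therefore deliberately not reproduction
targets.

## Numerical choices and degenerate inputs

* Sightline comparisons use a relative tolerance of 1e-9·(1 + |z₀| + |z₁|);
  grazing contact counts as visible.
* Empty ratios (empty region, zero viewshed, empty matrix) raise
  `UndefinedRatioError` rather than returning NaN.
* `point_to_cell` at the outer boundary: the west and north outer edges are
  in-extent, the east and south are not — the price of a consistent
  larger-index rule on interior edges.  Cell centres are never on edges.
* Percentile rule everywhere: linear interpolation between order statistics.
* Wilcoxon with all-zero differences returns V = 0, p = 1 (the
  identical-samples convention); a zero-variance paired t raises
  `DegenerateSampleError`.
* κ with chance agreement 1: returns 1 if observed agreement is also 1,
  otherwise raises.

## Known limitations

* The exact sightline test is O(path length) per ray; viewsheds are
  union-over-observers with nearest-first early exit.  Fine at desk scale,
  not at province scale.
* No earth curvature/refraction; no vegetation; no morphological
  post-processing of cliff maps (patch merging, minimum mapping unit).
* The synthetic road network is a lattice, not a road graph; the terrain
  has no lithology or drainage.
* GeoTIFF is not read; rasters are ESRI ASCII Grid only.
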