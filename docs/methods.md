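# Methods

## Coordinate and mask conventions

Coordinates are 0-based with `x` = column, `y` = row and the origin at
the image's top-left.  A tile anchored at `(ox, oy)` with side `T`
covers the half-open region `[ox, ox+T) × [oy, oy+T)`, so pixel
membership in a tile is unambiguous.  Instance masks are stored cropped
to their bounding box with a global offset; areas are exact pixel
counts.

Color inputs are reduced to a single channel by luminance average
before any processing; all stages operate on grayscale.

## Sliding-window tiling

Default geometry: 512 px square tiles every 256 px (half-tile stride).
Per axis the tile origins are the multiples of the stride for which the
tile lies fully inside the image; when the dimension is not
stride-aligned, one final origin clamped to `dim − T` is appended.
Clamping (rather than padding the right/bottom edge) keeps every tile
fully inside real data, so a detector never sees synthetic border
pixels; the cost is duplicated coverage near two image edges, which the
duplicate-suppression stage absorbs.  Images smaller than one tile are
the only padded case (zero-padding up to `T`), and that padding is
stripped when detections are reprojected to global coordinates.

With the default half-tile overlap, every object whose diameter is
below `T − s = 256 px` appears fully interior to at least one tile — the
property that motivates overlapping tiles in the first place.

## Cross-tile duplicate suppression

Detections from tiles whose regions overlap are compared pairwise; the
intersection area is taken as a fraction of each instance's own area,
and the pair is a duplicate when the **larger** of the two ratios
strictly exceeds the threshold θ (default 0.30).  The max-ratio rule is
a deliberate choice where "overlap by more than 30%" is ambiguous: a
small fragment clipped at a tile edge overlaps its full-size
counterpart by nearly 100% of its own area but possibly by much less
than 30% of the larger instance's, and removing exactly such fragments
is the purpose of the procedure.  Both the threshold and the rule
(`max`/`min`) are configurable.  Instances from the same tile are never
duplicates — side-by-side objects within one tile are distinct by
construction.

Suppression is formulated over connected components of the duplicate
graph: in each component only the largest-area instance survives, with
ties broken toward the smaller `(origin_y, origin_x, id)`.  The
component formulation is independent of tile processing order.  For the
graphs the tiling actually produces — fragments of one object, all
overlapping the full-size "hub" instance — it reaches the same fixed
point as repeatedly deleting the smaller member of any duplicate pair;
for adversarial chains whose end instances do not overlap each other
the two formulations can differ, and the component rule (one survivor
per physical organoid) is the behaviour this toolkit defines.
Survivors are renumbered 1..n in raster order of their centroids for
stable, human-readable ids.

## Segmentation backends

A backend is any callable taking a `T×T` single-channel array and
returning `(mask, confidence)` pairs in tile coordinates.  The trained
CNN detectors used in practice are exactly such callables; this package
ships a classical **reference detector** so the whole pipeline runs
with no trained weights:

1. Gaussian smoothing (σ = 2 px).
2. A robust global threshold on dark structures: organoid rims sit well
   below the background median in bright-field.  The threshold is
   `median − max(k·σ_n, 0.05·range)` with `k = 5`, where σ_n is the
   noise sd after smoothing, estimated structure-free from the
   smoothing residual (1.4826·MAD).  On a blank noise tile essentially
   no pixel clears it — this is the blank-tile guard.  The rule assumes
   background-majority tiles, valid for sparse organoid cultures.
3. Hole filling (recovers the bright lumen enclosed by the rim),
   connected components, and a distance-transform watershed to split
   touching blobs.  Watershed seeds must be at least
   `max(15 px, 1.5 × inscribed radius)` apart, so single convex blobs
   are not split while touching equal-size blobs are.
4. A minimum-area filter (default 50 px).

Confidence is a shape score — circularity `4πA/P²` for cystic
(spherical) mode, convex-hull solidity for budded (lobed) mode —
clipped to [0, 1].  It is semantically different from a CNN's learned
probability but lives on the same scale, so the threshold machinery is
identical.  The default confidence thresholds (0.795 cystic, 0.836
budded) follow the calibration reported for the trained detectors and
are carried as configuration constants; threshold comparison is `≥`.
Budded organoids may be over-split by the watershed (their lobes mimic
touching blobs); a trained backend is the intended detector for
production use.

External masks load from label-image TIFF (0 = background, k = id;
lossless round-trip with a detection set) or VGG Image Annotator
project JSON (polygon/polyline regions only; self-intersecting polygons
are rejected with their region index).  Polygons are rasterized with
the pixel-center rule: pixel `(r, c)` covers `[c, c+1) × [r, r+1)` and
belongs to the polygon iff its center `(c+0.5, r+0.5)` lies inside, so
an axis-aligned 10×20 rectangle rasterizes to exactly 200 px.

Augmentation operators (horizontal/vertical flip, random zoom-crop,
random Gaussian blur, random brightness/contrast) are deterministic
given a seed, return the original dimensions, and clamp intensities to
the dtype's valid range.  They are provided for training external
detectors; no training happens in this package.

## Cell-count regression

`log N = β₀ + β_A·log A + β_S·S + β_M·M + ε`, ordinary least squares on
training rows (area in px, binary covariates, reference nuclei count).
Logs are natural internally; the base is recorded in the model file,
and fitting is equivariant under a base change (coefficients rescale,
predictions are identical), so the choice is presentation only.  The
extended variant adds the raw perimeter and the area-to-perimeter ratio
as predictors; note these are nearly collinear with area for
circle-like organoids, which mirrors the weak gain reported for such
extensions.

Rank-deficient designs (e.g. a constant covariate column) raise an
error naming the degenerate column rather than silently dropping it.
Models serialize to versioned JSON and round-trip exactly; a schema
version mismatch or corrupt file is an error, never a partial model.

Per-organoid predictions are `N̂ = exp(·)` with a rounded variant
`max(1, round(N̂))`.  The **well total sums the unrounded estimates**:
rounding first injects up to 0.5 cells per organoid of bias; the
rounded sum is reported as a secondary figure.  Estimating a well
requires a deduplicated detection set — passing a pre-suppression set
would double-count organoids and is rejected.

No prediction intervals are produced; the residual sd is stored in the
model file so they can be added downstream.

## Evaluation metrics

- Per-organoid error: `log10(real / predicted)`, aggregated as the mean
  of absolute values with a t-based 95% CI; the signed mean is also
  reported.
- Per-well error: `100·|real − estimated| / real` percent.
- Detection: greedy one-to-one matching in descending confidence at a
  mask-IoU threshold (default 0.5, configurable), and single-class mAP
  as the area under the all-points-interpolated precision-recall
  envelope.
- Threshold selection: a classical ROC needs a fixed negative count,
  which a detection task lacks, so the confidence threshold is chosen
  on a surrogate curve — recall against spurious detections per image
  min-max normalized over the candidate grid — maximizing the
  Youden-style objective `TPR − normalizedFP`, ties to the smallest
  threshold.  The full curve is returned for inspection.

## Synthetic wells

The generator emulates what the pipeline consumes: a 2048 px grayscale
well (configurable) with ~80 non-overlapping organoids whose areas are
log-normal (default median `e⁸ ≈ 3000 px²`, i.e. ~60 px diameters at
the 4× magnification scale this targets), rendered as a dark rim
(background − 70 grey levels) around a bright lumen (background + 40)
on a noisy (σ = 6) lightly blurred (σ = 1.2 px) background at
background level 128.  Budded organoids add 2–5 lobes to the base
ellipse.  Placement is rejection sampling with a minimum bounding-box
gap (4 px) so truth masks are pairwise disjoint; if fewer than 90% of
the requested organoids fit, generation fails reporting the achieved
count.

Cell counts follow the same log-linear law the regression fits, with
multiplicative noise: `N = max(1, round(exp(β₀ + β_A ln A + β_S S +
β_M M + ε)))`, `ε ~ N(0, σ_ε)`.  The default law (β₀ = 0.5, β_A = 1.0,
β_S = −0.2, β_M = −0.3, σ_ε = 0.2, natural-log space) is an invented,
plausible setting — no coefficients are published for real organoids —
with counts scaling essentially linearly in area and tumor/budded
organoids somewhat denser, matching the reported direction of those
covariates.  Because counts are integers, a zero-noise fit recovers the
law only to rounding precision (~1e-3 on coefficients at N ~ 3000);
exact-recovery checks therefore use constructed tables whose counts are
exactly integral under the law.

Not emulated: Matrigel texture, debris, touching/overlapping organoids,
uneven illumination, focus gradients, dead cells.  Tests passing on
this material validate the geometry and bookkeeping of the pipeline —
tiling, suppression, counting, metrics — not detector robustness on
real wells.

## Problem sizes and numerical choices

Test and acceptance runs use 1024 px wells with ~12 organoids (9 tiles;
diameters < 256 px so every organoid is interior to some tile), 100
random blob layouts of ≤ 50 discs for the suppression-oracle
equivalence, 50 wells for the end-to-end count identity, and ~3,200
generated organoids (8 wells × 100 organoids × 4 tissue/morphology
conditions) for regression recovery — sizes chosen so the full suite
completes in a couple of minutes on one CPU while keeping every check
statistically meaningful.  Coefficient recovery is asserted within 3
standard errors; CI coverage over 50 replicates (n = 1000, σ = 0.2)
must land in [0.85, 1.0]; held-out mean |log10 RE| is compared to the
closed form `σ_ε·√(2/π)/ln 10` for Normal log-errors (≈ 0.0693 at
σ_ε = 0.2) within 0.01.

The perimeter of a mask defaults to the Crofton 4-direction estimate
(reduces the square-vs-diagonal bias of edge counting and makes a
disc's circularity ≈ 1); an exact pixel-edge count is available as an
option and is the one verified against a brute-force boundary walk.
Neither is asserted to be "the" perimeter of any external dataset —
the definition is a documented choice.

CSV outputs are comma-separated UTF-8 with a header row and 4-decimal
fixed formatting so repeated runs with the same seed are byte-identical;
every CLI command writes a `run_config.json` provenance record
(resolved parameters, seed, package version).

## Known limitations

Area-based counting cannot see dead cells, lumen-size changes or other
density shifts; estimates drift under treatments that alter cell
density (e.g. toxin-induced lumen swelling or cytotoxic co-culture
shrinkage).  The reference detector assumes dark-rim/bright-lumen
appearance on a background-majority tile and is a development/testing
stand-in, not a replacement for a trained instance-segmentation
backend.  Overlapping organoids are neither generated nor specially
handled: suppression assumes overlap across tiles implies identity,
so two genuinely overlapping organoids detected in different tiles
could be merged.
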