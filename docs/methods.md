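# Methods

This note records the models, conventions and numerical choices behind
`spikegrain`, in the spirit of a statistics package's model documentation.

## The measurement model

One image shows the threshed grains of a single wheat spike arranged by
spikelet position — paired rows from the bottom of the spike to the top —
on a dark background, with a reference object of known physical length at
the side. All quantities are reported in millimetres after calibrating
pixels against that reference (`px_per_mm = line_px / known_mm`). The
calibration is *global* to a session: one scale applies to every image,
mirroring a fixed camera-to-sample distance.

Segmentation reproduces the classical interactive chain:

1. RGB is collapsed to luminance (ITU-R BT.601 weights).
2. A threshold is recomputed **per image** (default Otsu; IsoData and a
   fixed threshold are selectable). A constant image yields an empty
   mask with a warning, not an exception.
3. Particles are 8-connected components with holes filled (grains are
   solid); components below a physical area limit (default **2.5 mm²**)
   are discarded as non-grain material. This one filter also removes the
   rendered scale bar (2 mm² by construction).
4. Grains are ordered bottom-left → top-right. "Bottom" is the maximal
   pixel-row coordinate, since raster row 0 is the top of the image.
   Rows come from 1-D gap clustering of centroid heights: sorted
   bottom-to-top, a new row starts where consecutive centroids are more
   than half the median grain height apart. An optional row-count hint
   instead splits at the largest gaps. Regions split the row list into
   contiguous thirds — ceil(r/3) bottom rows, floor(r/3) top rows, the
   remainder middle (so middle ≥ top). With fewer than three rows no
   thirds exist: grains are tagged "middle" but region-level statistics
   are reported missing.

## Morphometric conventions

* **Area** is the pixel count of the filled particle, scaled to mm².
* **Boundary** is the marching-squares iso-0.5 contour of the mask
  (sub-pixel vertices). On a *binary* mask this contour is a staircase
  whose corners inflate arc length by 5–7% on smooth outlines, so the
  **perimeter** and the **minimum caliper width** are measured on a
  lightly smoothed contour (circular moving average, window 5; vertices
  are ~0.7 px apart). Window 5 was chosen by measuring rasterized disks,
  rotated ellipses and rectangles against closed forms: it cancels the
  staircase (disk/ellipse perimeter error ≤ 0.5%) while shrinking
  rectangle perimeters by at most ~1.4%. Contours of ≤ 7 vertices are
  left unsmoothed so single-pixel particles keep their diamond outline.
* **Feret** (maximum caliper diameter, the grain-length proxy) is the
  largest pairwise distance over the convex-hull vertices of the *raw*
  contour — extreme points must survive smoothing. **MinFeret** (the
  grain-width proxy) uses rotating calipers on the smoothed contour's
  hull: the minimum over hull edges of the farthest vertex distance to
  the edge's supporting line. Collinear outlines degrade to segment
  length / one pixel width and are flagged.
* The **best-fit ellipse** takes orientation and axis ratio from central
  second moments (pixels as unit squares, +1/12 per axis) and is rescaled
  so π/4·major·minor equals the particle area (equal-area convention).
  Regions with zero raw variance in some direction fall back to the pixel
  extent, flagged.
* **Shape descriptors**: circularity = 4πA/P² capped at 1.0 (coarse
  rasters can exceed 1), aspect ratio = major/minor, roundness =
  4A/(π·major²), solidity = A over the convex-hull area of the pixel
  *corners* (so a filled rectangle has solidity exactly 1).
* Angles are degrees in [0, 180) with the y axis pointing up.

At 10 px/mm these conventions give ≤ 1% error on area, ≤ 2% on Feret and
MinFeret, disk circularity ≥ 0.98 and 2:1-ellipse roundness 0.50 ± 0.02
against analytic values (verified in the acceptance suite).

## ISVAD

For a grain-size parameter x over the N grains of one spike,

    ISVAD: sigma = sqrt( sum_i (x_i - mu)^2 ) / sqrt(N)

— the **population** standard deviation, divisor N, not the sample
divisor N−1. The population form is retained deliberately; note its
expectation under i.i.d. sampling with true SD s is
c₄(N)·s·√((N−1)/N) ≈ s·(1 − 3/(4N)), which the recovery checks account
for. ISVAD is computed for width (MinFeret), length (Feret), area and
perimeter, per whole spike and per region; region values use the
region's own mean. A single grain has ISVAD 0.

Derived indices: percent decrease 100·(control − stress)/control,
displayed with half-up rounding at one decimal (half-up, not banker's:
6.25 → 6.3; eight guard digits absorb binary float representation error
first); and the heat susceptibility index in the Fischer & Maurer (1978)
form HSI = (1 − Y_stress/Y_control)/D with D = 1 − grand-mean(stress)/
grand-mean(control). The HSI formulation is an interpretation — the
index is often cited without a formula — and is documented as such.

## The synthetic generator

`SpikeSimConfig` renders grains as anti-aliased filled ellipses (local
4× supersampling averaged to pixel coverage), long axis vertical ± a
rotation jitter (default ± 8°), on a regular grid sized so that no grain
comes within 3 px of another or of the border; impossible spacings raise
a layout error rather than rendering touching grains. A vertical scale
bar (10 mm × 0.2 mm) occupies a reserved left margin. Pixel noise is
Gaussian, clipped to [0, 1], optionally with a linear illumination ramp.
Everything derives from one seed and is bit-reproducible.

Defaults are field-realistic for a healthy spike: 20 spikelet rows × 2
grains, mean grain 7.0 × 3.5 mm (≈ 19 mm² projected area, inside the
3–30 mm² range real grains span), within-spike SDs 0.62 mm (length) and
0.37 mm (width) — figures of the order reported for non-stressed wheat —
at 10 px/mm. Grain sizes are sampled independently per grain; draws with
width > length are resampled (swapped as a last resort). Two sampling
modes exist: independent length/width SDs, or `sd_area_mm2`, which draws
the projected area directly at a fixed length/width ratio so the true
within-spike area SD is exactly the configured value (used by the
recovery checks). `region_effects` multiplies the linear dimensions of
bottom/middle/top grains, scaling both the mean and the spread of a
region. `add_speckles` scatters sub-grain debris disks that touch
nothing, for testing the area filter.

What the generator does **not** emulate: real grain texture, crease and
shading, shadows, awns or rachis fragments, touching grains, JPEG
artefacts, perspective or lens distortion, and uneven backgrounds beyond
a linear ramp. Tests passing on synthetic images therefore demonstrate
the correctness of the measurement chain under the stated geometry and
noise, not robustness to every property of real photographs; the
validation-statistics module exists precisely to calibrate image values
against physical reference measurements on real material.

## Validation and trial statistics

* `fit_calibration` is ordinary least squares of the reference (caliper)
  values on the image values, R² = 1 − SSE/SST (defined as 0 for a
  constant response).
* `kfold_cv` shuffles observations with a seed, splits into k near-equal
  contiguous folds, fits the line on each complement and predicts the
  fold; it reports per-fold mean absolute error and MSE and the square
  root of the mean of fold MSEs. With k = n it reproduces the
  closed-form leave-one-out residuals e_i/(1 − h_ii) to 1e-8.
* `anova_split_plot` handles balanced designs with one observation per
  block × environment × genotype cell: environments (main plots) and
  blocks are tested against the block × environment stratum, genotype
  and G×E against the residual. A table with a multi-level `year`
  column is analysed combined, with (year, block) pairs as blocks.
  Unbalanced tables are rejected rather than approximated.
  `anova_factorial` provides the plain two-way RCBD alternative, since
  the appropriate error strata for a given trial are a modelling choice.
* `dmrt` ranks means descending and compares a pair p ranks apart
  against the Duncan critical range R_p = q(α_p, p, df)·√(MSE/n) with
  protection level α_p = 1 − (1−α)^(p−1); studentized-range quantiles
  come from `scipy.stats.studentized_range` (accuracy well beyond the
  1e-4 needed). Letters are the insert-and-absorb display over maximal
  runs of consecutive ranked means in which *every* inner pair is
  non-significant — slightly stricter than testing only the extremes of
  a run, and it guarantees that groups sharing a letter never differ by
  more than the applicable critical range (verified against brute-force
  pairwise checks on randomized configurations).

## Problem sizes and determinism

The test and acceptance runs use sizes chosen to exercise the statistics
meaningfully at desk scale: 50 spikes (10–25 rows, noise SD ≤ 0.05, 30
injected speckles each) for count fidelity; 200 spikes of 40 grains for
ISVAD recovery at area SDs 0.5/1/3 mm²; 300 null simulations for p-value
uniformity; 100 randomized 6-group configurations for the Duncan letter
invariant. Every stochastic component takes an explicit seed; CSV bodies
are written with fixed 3-decimal formatting (a `full_precision` switch
writes raw floats) so a re-run of a fixed session is byte-identical.

## Known limitations

* Published field results (trait tables, R² of the caliper validation,
  trial ANOVA p-values) depend on raw data that is not published;
  they are not recomputable and are not claimed.
* The perimeter estimator targets low bias against analytic shapes, not
  numerical identity with any particular interactive tool's weighted
  pixel-edge count; likewise the exact auto-threshold variant of such
  tools is a documented choice (Otsu by default), not an emulation.
* Watershed splitting of touching grains is out of scope: the protocol
  guarantees separated grains, and the generator enforces it.
* The split-plot ANOVA requires balance; mixed-model/REML analysis of
  unbalanced trials is out of scope.
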