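# Methods

This note records how each quantity is defined and estimated, which
defaults were chosen where the procedure is genuinely open, and what
the synthetic phantoms do and do not establish about real data.

## Image model and preprocessing

Input volumes are non-negative intensity grids (depth × y × x) with
caller-supplied lateral/axial spacing in µm; all arithmetic is done in
float64 regardless of on-disk bit depth. The depth maximum-intensity
projection (MIP) is the working 2D image.

**Hb content** (a.u./mm²) is Σ intensity / imaged area computed on the
raw MIP only; the API rejects enhanced images because histogram
equalisation redistributes intensity and would bias any intensity-sum
metric. The metric is linear in intensity and has no absolute
calibration — it is comparable within an instrument and gain setting,
not across them.

**Enhancement** is CLAHE followed by Gaussian smoothing, output
rescaled to [0, 1].
Defaults: 8×8 tiles, clip limit 0.01, smoothing σ = one pixel's
physical size. The tile/clip values follow common practice for
vascular imagery; the σ convention makes 5 µm and 20 µm scans receive
the same *physical* smoothing. All three are exposed in the config and
CLI. A constant image is returned as constant zero (rescale
convention).

## Segmentation

Default thresholding is Otsu's method on a 256-bin histogram of the
enhanced image (constant images are rejected — no threshold exists).
The adaptive alternative thresholds against a local mean over a window
of configurable physical size (default 200 µm) with sensitivity
s ∈ [0, 1]: a pixel is foreground when it exceeds the local mean by
(0.5 − s) × dynamic range, so s = 0.5 is the plain local mean and
larger s admits dimmer pixels. Adaptive thresholding is the remedy of
choice when superficial capillaries crossing brighter vessels fragment
under a global threshold.

Cleanup removes connected components smaller than `min_object_px` and
fills holes below the same cutoff, so genuine avascular gaps survive.
Default `min_object_px` is the pixel area of a disk whose diameter is
twice the 7.5 µm optical spot (floor 4 px): structures below the
resolution limit cannot be real vessels, and the physical scaling keeps
the cutoff consistent across scan pitches. No cleanup rule is part of
the measurement definitions; it is an engineering stage with documented
defaults.

## Skeleton graph

The mask is thinned to a one-pixel 8-connected skeleton
(topology-preserving). Skeleton pixels with ≥ 3 skeleton neighbours
are clustered by 8-connectivity into branch nodes (thinning produces
junction "blobs"; without merging, each blob spawns spurious short
segments). Maximal node-to-node pixel chains become ordered segments;
diagonal steps count √2 × pixel size toward length, which makes length
unbiased on 8-connected chains. Isolated cycles are closed chains
attached to no node.

**Spur pruning**: segments running from a free endpoint to a branch
node and shorter than `prune_len_um` (default 22.5 µm = 3× optical
spot) are thinning artifacts of thick vessels; their pixels are removed
and the graph re-derived once from a re-thinned skeleton, so residual
junction pixels of degree 2 merge back into through-going segments.
One pass only — pruning is idempotent at fixed length. Isolated short
segments are *not* pruned (they may be genuine capillary fragments;
mask cleanup already handles speckle).

**Radii**: the Euclidean distance transform of the mask evaluated along
the centerline, minus half a pixel — the transform measures to
background pixel *centres*, half a pixel beyond the vessel wall —
floored at half a pixel (the radius of a 1-px line). Without this
correction diameters are biased high by one pixel across all widths.

Segments shorter than `min_segment_um` (default 2× pixel size) carry
no usable angle information; they are excluded from per-vessel metrics
but retained in the mask, so fill fraction is unaffected.

## Per-vessel estimators

**Diameter** = 2 × mean radius over path points whose arc distance from
both segment ends is at least the point's own radius (near an end the
distance transform reads the end cap, not the wall, biasing the
estimate low). Segments too short to exclude their ends fall back to
all points and are flagged. On noise-free straight-tube phantoms the
estimator is exact; with default blur and noise the width-sweep mean
absolute error at 5 µm pitch is well under one pixel. Resolution is
pixel-limited: a 1-px-wide line reads ≈ one pixel regardless of its
true sub-pixel width.

**Tortuosity** (°/µm) = Σ |turning angle| / arc length. The raw pixel
chain quantises directions to multiples of 45°, which would make the
angle sum resolution-dependent, so the path is first resampled at
uniform arc-length steps (default 2× pixel size) and turning is
measured between consecutive chord directions. Absolute values depend
on the resampling step — the step is recorded with every run, and
cross-study comparisons should match it — but contrasts between groups
processed identically are step-independent to first order. Paths
shorter than two steps have undefined tortuosity and are excluded from
medians. Analytic checks: straight path → 0; full circle of radius
r → 360/(2πr) within 1.6 % at step = r/10; single right-angle corner
of total length L → 90/L.

Per-image summaries are medians across metric-eligible segments;
vessel count is the number of such segments. Note that "vessel" here
means a branch-to-branch centerline segment: a biological vessel
crossing others contributes several segments. Counts are therefore
comparable between groups processed identically, not absolute
anatomical counts.

## Group statistics

Analysis units are locations, or mice (median across each mouse's
locations — avoiding pseudo-replication). Groups are compared with an
unpaired two-tailed t-test; Student's pooled-variance form is the
default reading of "unpaired t-test", Welch's form is a flag, and the
choice is recorded in the report. Sample SDs use n−1. Two identical
constant groups are reported as p = 1 with a degeneracy flag rather
than 0/0. Empirical type-I error at α = 0.05 over 1000 null
simulations at n = 8 sits within [0.03, 0.07] (recomputed by the
acceptance script). No multiple-testing correction is applied across
the five parameters; with four or five families this understates
family-wise error — a documented limitation of the protocol, not of
the implementation.

## Synthetic phantoms

The generator emulates hemoglobin-contrast microscopy: dark
background, bright tubes of 1–15 px width, Gaussian PSF of 7.5 µm
FWHM (the optical spot), additive Gaussian noise at a configurable
SNR (default 10), default field 340×340 px at 5 µm pitch (1.7×1.7 mm²,
a typical fine-pitch region of interest). Identical spec + seed is
bit-reproducible.

**Centerlines** integrate a sinusoidal curvature wave — random
wavelength 120–240 µm and phase, carrying 85 % of the requested
turning rate (a sinusoid of peak curvature c has mean |curvature|
2c/π) — plus von Mises white heading jitter for the remaining 15 %,
whose concentration κ is obtained by numerically inverting the exact
E|θ| integral of the von Mises distribution (cached Brent root-find;
for κ → 0 the mean saturates at 90° per step). Walk vertices are
interpolated with a chord-length-parameterised cubic spline, and
**truth tortuosity is evaluated analytically on the resulting fine
polyline**, before any rasterization — the pipeline is scored against
a resolution-independent quantity.

Why not pure white-noise headings: they place all turning at the
single-step scale, giving centerline curvature radii smaller than the
tube half-width. A tube cannot bend tighter than its own radius and
remain a tube in the raster — the medial axis of the drawn mask is
then necessarily straighter than the generating polyline, the "truth"
is unrepresentable in the image, and all morphologies converge to the
same measured tortuosity. The sinusoidal form keeps the turning at
wavelengths the mask (and any real image of such a vessel) can
express.

**Presets.** The group contrast of interest is carried by fill
fraction 9.6 % vs 17.1 % and a 1.57× turning-rate ratio
(normal vs hypervascular skin). Absolute rates are 1.5 and
2.355 °/µm with width medians 30 and 18 µm (lognormal, σ = 0.25),
chosen so every centerline's curvature radius stays at or above the
tube half-width and above the PSF scale — the representability
condition above. Vessels enter from a random border heading inward;
under a fill target, vessels are added until the truth mask reaches
the target (±10 % band), redrawing candidates that would overshoot,
and an unreachable target raises an error stating the fill achieved.

Volumetric phantoms place vessels on 2–3 depth layers with a peaked
axial intensity profile, so the depth MIP recovers the 2D scene.

**What phantom results do not show.** The phantom has additive
Gaussian noise only (no speckle, shot noise, or acoustic artifacts),
no hair/melanin absorbers, no depth-dependent sensitivity, and vessel
amplitude is constant rather than perfusion-weighted. Passing
recovery tests on phantoms demonstrates the estimators and their
implementation, not robustness to every real-world artifact; on real
data the adaptive binarization and the smoothing scale are the knobs
that matter most.

## Numerical conventions and degenerate inputs

* Coordinates are 0-based (row, col); all exported paths use this
  convention. Degrees throughout, matching the °/µm unit.
* Chain tracing and junction assignment break ties lexicographically,
  making graph extraction deterministic.
* Empty mask → empty skeleton → record with count 0, fill 0 %, absent
  medians. Absent values propagate as missing (never 0) into group
  tables, and medians/aggregations ignore them, reporting n.
* Otsu on well-separated modes has a plateau of equally optimal
  thresholds (empty histogram bins); any plateau member maximises the
  between-class variance and downstream masks are identical.
* The whole pipeline is deterministic given config + inputs; phantom
  generation is deterministic given spec + seed. Metric CSVs reproduce
  byte-identically.

## Problem sizes used in the shipped checks

Cohort experiments use 10 images per group at the default 340×340 px
field; the width sweep uses 4 parallel tubes per image over 5 seeds;
segmentation overlap uses 20 phantoms at SNR 5 (192×192 px); the null
calibration uses 1000 simulated comparisons at n = 8. These sizes give
stable statistics (group-mean SEs a few percent of the contrasts)
while keeping any single check in the seconds-to-a-minute range.
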