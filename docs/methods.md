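# Methods

## Problem and model

Pollen viability is scored by dye exclusion: acetocarmine stains the
cytoplasm of intact (viable) grains red, while non-viable grains remain
transparent. On a bright-field micrograph this reduces viability scoring to
(i) finding every grain and (ii) deciding per grain whether it is stained.
`pollenvia` implements both stages with classical image processing and a
linear classifier; nothing is learned end-to-end, so every stage is
individually testable against analytic oracles.

## Segmentation

Stages, in order: grayscale conversion (ITU-R 601 weights 0.299/0.587/0.114,
rounded half away from zero); Canny edge detection (Gaussian sigma 1.4,
hysteresis thresholds 50/150 on the 8-bit scale); morphological closing with
a disk footprint (5 px kernel, 1 iteration) to bridge small edge gaps; hole
filling to turn closed edge loops into solid regions; marker-based watershed
on the Euclidean distance transform, with markers at distance-transform
local maxima separated by at least 15 px, to split touching grains.

Design choices made where the procedure was genuinely open:

- **Canny on grayscale, not on the Sobel magnitude.** Canny differentiates
  internally; running it on a gradient image double-differentiates and
  thins real edges. The Sobel stage (`gradient_highlight`, unnormalized 3×3
  kernels, reflective borders) is kept as an optional pre-enhancement behind
  `SegmentationConfig.use_gradient_highlight`.
- **Watershed markers.** Every connected component is guaranteed at least
  one marker (if peak suppression removes all of a component's maxima, the
  global distance maximum of that component is used), so components never
  vanish and disjoint components never merge.
- **Contours and measurements.** The outer contour is the longest
  marching-squares level-0.5 polyline of the filled region; perimeter is its
  polygonal arc length; area is the exact filled pixel count. Circularity
  `4πA/P²` is not clamped: digitized shapes can slightly exceed 1, and the
  marching-squares perimeter overestimates a circle's circumference by
  ~5–8 %, so an ideal digitized disk measures ≈ 0.87.
- **Acceptance filter.** Regions with circularity ≤ 0.5 or area ≤ 100 px are
  discarded (strict inequalities; boundary values excluded). The thresholds
  are raw pixel quantities — no µm calibration is attempted.
- **Border policy.** Regions whose bounding box touches the image border are
  dropped by default (their shape statistics are unreliable); configurable.
- Coordinates are 0-based, x = column / y = row; bounding boxes half-open.

## Feature set

The 19-value per-grain descriptor is split 10 geometric / 2 texture /
7 color, in a frozen documented order (`FEATURE_NAMES`). Geometric moments
(axis lengths, eccentricity, solidity, extent) come from the region's filled
pixel set, not the contour. Texture is the population (n-divisor) grayscale
SD and the Shannon entropy (bits) of an 8-bin histogram over [0, 256) — the
two simplest summaries of how intensities are distributed inside the grain.
Color features are the RGB channel means (8-bit scale), the HSV means (hue
averaged circularly and reported in degrees [0, 360) so red hues near 0° and
360° do not cancel; S, V in [0, 1]) and the fraction of region pixels whose
red channel strictly dominates. The red-vs-blue contrast is what makes the
two classes linearly separable — verified as a property test.

Feature standardization (`FeatureScaler`) stores per-feature mean and
population SD; zero-variance features get SD 1 so scaling is a no-op rather
than a division by zero. The scaler is always fitted on the training portion
only.

## Classifier and training protocol

`ViabilityClassifier` is a scikit-learn-compatible estimator wrapping a
soft-margin linear SVM (liblinear, C = 1.0 by default, solver iteration cap
500, tolerance 1e-5). The protocol is fixed: a seeded stratified 70/30
split, scaler fitted on the 70 %, SVM fit in scaled space, validation
accuracy measured on the held-out 30 % and stored in the model metadata.
Class encoding is viable = +1, non-viable = −1; the decision rule is
`margin = w · scaled(x) + b`, viable iff margin > 0, with margin exactly 0
conservatively classified non-viable.

The stratified split is implemented so that the selected row indices depend
only on the class partition, not on which class is named viable (classes are
processed in order of first occurrence, per-class permutation from one seeded
generator). This makes label-swap symmetry — swapping all labels negates
every margin — hold to solver precision, and makes training bitwise
deterministic for a fixed seed. Training uses per-grain feature rows (not
per-image aggregates). Models serialize to versioned, human-readable JSON
(weights, bias, scaler parameters, training metadata); serialization is
canonical, so two saves of one model are byte-identical.

## Synthetic slide generator

The generator emulates what the pipeline assumes about real slides, with
exact per-grain ground truth:

- Bright background (level 225/255) with a linear left-to-right illumination
  ramp (default total change 10 units).
- Grains are mild ellipses (axis ratio uniform in [0.85, 1.0], random
  orientation), radius Normal(15, 2) px truncated at 5 px — near-circular by
  construction so their circularity clears the 0.5 filter. The recorded
  ground-truth radius is the area-equivalent radius √(ab).
- Viable grains are filled with a stain-like red (mean RGB (178, 44, 74),
  per-grain jitter SD 6); non-viable grains get a background-like interior
  (mean (232, 222, 224)) with a dark 2.5 px rim so their outline remains
  Canny-detectable — the "transparent" appearance.
- Placement is rejection sampling (2000 attempts per grain, then a
  "scene too crowded" error). With `touching_fraction = 0` every center pair
  is separated by more than the radius sum plus 3 px (the package guarantees
  > 2 px); a `touching_fraction` of the grains is instead attached to a
  random earlier grain at 0.80–0.95 of the radius sum, overlapping it.
- Small dark debris specks (radius 1–3 px, default 6 per scene) are placed
  clear of grains; their area is far below the 100 px filter, so they test
  the filter rather than the classifier.
- Gaussian pixel noise (default SD 3, 8-bit units) is added last and the
  image clipped to [0, 255].

One `numpy` generator seeded per scene drives all draws in a fixed order, so
identical parameters give byte-identical images. What the generator does
*not* emulate: optics (point-spread function, chromatic aberration, focus
gradients), 3D grain stacking, partial staining, and realistic debris
morphology. Passing the validation here therefore demonstrates that the
pipeline is correct and self-consistent under the stated appearance model,
not that it meets the same accuracy on arbitrary real slides — on real data
the segmentation thresholds and the trained model would need to come from
annotated real images via the same `train` workflow.

## Validation design and problem sizes

The package's headline check mirrors the tool-validation design of comparing
automated against visual per-image counts with Pearson correlation, with the
generator's ground truth standing in for visual counts (the original
visual-count corpus is not published). The suite trains on 400 labeled
synthetic grains per class and scores 60 slides with true viable counts
uniform in 5–40 and non-viable in 2–15, touching fraction ≤ 0.1, noise SD
≤ 5; the resulting per-class correlations are required to reach at least the
published operating levels (r ≥ 0.98 viable, r ≥ 0.96 non-viable), treated
as lower bounds since clean synthetic scenes are easier than real slides.
These sizes keep the full suite fast while leaving the correlation estimate
stable across seeds (observed r ≈ 0.999 for both classes).

Pearson r is computed with the closed-form sum formula; a constant count
vector yields an explicit "undefined" flag rather than NaN. An image with
zero detected grains reports PolVia as undefined, never as 0 %.

## Numerical notes and limitations

- Perimeter bias: marching-squares perimeters of digitized disks are ~5–8 %
  above 2πr; the circularity filter threshold (0.5) is far from this bias.
- Grains touching in chains (three or more) can under-split when their
  distance-transform peaks fall within the 15 px suppression radius; at the
  simulated touching fractions (≤ 0.1) this is rare.
- `LinearSVC` may stop at the 500-iteration cap without converging on hard
  data; on separable standardized features it converges well before it.
- The exact historical 19-feature inventory is not published; this package's
  list matches the documented 10/2/7 geometric/texture/color split and is
  frozen as the canonical order here, so feature-for-feature equivalence
  with the original tool cannot be asserted.
- The CLI config file is YAML; unknown keys are rejected, and
  `dump_config(load_config(p))` is byte-stable.
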