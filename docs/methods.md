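# Methods

This note documents the measurement model behind `octfib`, the default
parameters and why they were chosen, and the numerical conventions that
matter for reproducing results.

## 1. Input model

A measurement site is an `OctImagePair`: an 8-bit grayscale reflectance image
(alveolar lumens dark, tissue bright, multiplicative speckle) and a
co-registered 8-bit RGB birefringence rendering in which hue encodes phase
retardance. Severity labels, when present, are one of `advanced`, `mild`,
`normal`.

## 2. Synthetic phantom generator (`octfib.phantom`)

Real PS-OCT lung data are typically proprietary, so validation uses phantoms
with recorded ground truth.

* **Geometry.** `n_alveoli` (default 30) non-overlapping, axis-aligned
  ellipses are placed sequentially: each new lumen is positioned at a sampled
  wall gap from a randomly chosen existing lumen along a random direction;
  placement retries against a dilated occupancy mask, and failure to place
  raises `PhantomPlacementError` (reporting how many were placed). Lumen
  areas and wall gaps are truncated-normal draws from class-dependent
  distributions; eccentricity (major/minor ratio) is uniform on [1, 1.5].
  Rasterization tests pixel centers, so recorded areas are unbiased pixel
  counts.
* **Calibrated class presets** (`class_presets()`): mean lumen areas
  81.5 / 88.6 / 131.8 px² and mean wall gaps 24.8 / 33.8 / 22.8 px for
  advanced / mild / normal; standard deviations are set to 20% of each mean
  (a design choice: wide enough to overlap, narrow enough to keep class
  orderings at cohort scale).
* **Reflectance.** Lumens at base intensity 20 on a wall background of 170,
  multiplied by log-normal speckle `exp(σ·g)` with σ = 0.2, where `g` is
  unit Gaussian noise smoothed with a 0.7 px Gaussian (spatially correlated
  speckle grains). These defaults were fixed at design time as the strongest
  noise at which ~80 px² lumens remain physically resolvable; stronger or
  coarser speckle erases the smallest advanced-class lumens regardless of the
  segmentation algorithm.
* **Birefringence.** A gray (zero-saturation) base image plus exactly
  `round(fraction × n_pixels)` colored pixels per hue band, drawn uniformly
  inside the band with saturation/value in [0.75, 0.95], placed on wall
  pixels. Presets: red 4.32 / 2.69 / 0.83%, yellow 6.50 / 5.86 / 2.88%,
  green 6.67 / 6.88 / 6.47%, blue 2.66 / 4.75 / 3.70% for
  advanced / mild / normal. The gray base guarantees that only the planted
  pixels fall inside any band, making ground truth exact up to hue-edge
  rounding.
* **Determinism.** Cohort item seeds derive from `numpy.random.SeedSequence`
  spawning, reduced mod 2³¹; the same cohort seed always reproduces the same
  images.

## 3. Color quantification (`octfib.colorfeat`)

The RGB birefringence image is converted to HSV; hue is scaled to [0, 180)
and saturation/value to [0, 255]. A pixel belongs to band *b* if
`hue_lo ≤ hue < hue_hi` **and** saturation ≥ 50 **and** value ≥ 50 (the
floors exclude gray/black background). Default bands: red [0, 20),
yellow [20, 40), green [50, 80), blue [90, 120); bands must be disjoint
(checked). Percentages use the full pixel count as denominator. The fibrosis
invasion fraction is `FiF = (Σ band percentages) / 100`.

## 4. Morphometry (`octfib.morphometry`)

### Segmentation

`segment_alveoli` chain: white top-hat of the **inverted** reflectance
(`255 − I`) with a disk of radius 12 px → Gaussian blur σ = 1.0 → Otsu
threshold → binary erosion ×2 → dilation ×2 → connected components
(8-connectivity) with region properties and ordered boundaries.

Rationale for inverting before the top-hat: lumens are *dark* structures
smaller than the disk, so on the inverted image they are exactly the bright
small-scale features the white top-hat isolates, while the flat bright
background and large-scale illumination cancel. Applying the top-hat to the
raw image instead responds only to speckle peaks (measured on phantoms:
precision ≈ 0.2 versus precision 0.998 / recall 0.974 / mean relative area
error 0.029 for the inverted form at default noise). A Canny edge map
(σ = 1.0) is computed by `canny_outlines` for QC overlays only.

### Wall thickness

From each lumen centroid, 16 rays at fixed equal angles step outward in
0.5 px increments; pixel lookup rounds with `floor(x + 0.5)` (plain
half-up rounding — `np.rint`'s round-half-to-even would bias half-integer
ray coordinates). The wall thickness along a ray is the distance from
exiting the source lumen to entering a *different* lumen, with both
boundaries refined to the midpoint between the last sample inside and the
first outside. Rays that leave the image, or whose measured thickness
exceeds `max_ray_px` (default 100), are discarded — the cap exists to
exclude spans to non-adjacent tissue. Geometry oracles: two circles of
radius 10 with centers 30 px apart yield 9.0 px against the analytic 10 px
(within the rasterization tolerance), and a hexagonal lattice (r = 15,
pitch = 50) yields a median of 21.5 px against the analytic 20 px.

### Filtering and summaries

Components are kept if area > 2 × `speckle_size_px2` (default 25 px², so
floor 50 px²) **and** area lies within the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the per-image area distribution (both rules
evaluated on the unfiltered distribution). Summaries report mean,
percentiles p10/p25/p33/p50/p67/p75/p90 (NumPy linear interpolation),
population standard deviation (ddof = 0) and range, for areas and pooled
wall samples; a summary with no alveoli or no wall samples is flagged
invalid and produces no feature row.

## 5. Features and balancing (`octfib.dataset`)

Alveoli are ordered by centroid column and grouped into patches of
`per_patch` = 10; a trailing group smaller than `min_last` = 5 is merged
into its neighbor. Each patch crops both channels identically and yields a
25-feature row: 10 area statistics, 10 wall statistics, 4 band percentages
and FiF (fixed column order in `FEATURE_COLUMNS`).

SMOTE oversamples every minority class to the majority count: neighbor
search uses z-scored features (k = 5 nearest same-class neighbors, k
lowered with a warning when the class is small; classes of size < 2 are
rejected); each synthetic row is `x + u·(x_nn − x)` with `u ~ U[0, 1]`
interpolated on the raw scale. Original rows are preserved bit-exactly and
provenance (`original`/`synthetic`) is tracked.

## 6. Classification (`octfib.classify`)

Default model: `GradientBoostingClassifier` (100 estimators, learning rate
0.1, depth 3); alternatives: decision tree, random forest, bagging,
logistic regression (standardized pipeline). Evaluation is stratified
k-fold (k = 10) with three balancing modes: `inside_folds` (default —
SMOTE refit on each training fold only), `before_cv` (balance once, then
split; reproduces protocols that balance the whole table), and `off`.
Fold predictions are pooled into one confusion matrix; accuracy is
`trace / total`. Per-class one-vs-rest precision, recall, specificity and
F1 carry explicit flags when a denominator is zero. Feature importances
are reported when ≥ 0.01, descending (normalized absolute coefficients for
the linear model).

## 7. Statistics (`octfib.stats`)

Mann–Whitney U uses the exact null distribution when the combined sample
size is ≤ 12 and there are no ties, otherwise the tie-corrected normal
approximation. One-way ANOVA raises `ZeroVarianceError` on degenerate
input. Tukey HSD returns all pairwise comparisons with significance at
α = 0.05. A Holm step-down adjustment helper is provided for the pairwise
panels. All are validated in the test suite against brute-force
enumeration and hand-computed sums of squares.

## 8. Validation problem sizes

The package's own acceptance scale (chosen to be desk-runnable, ~40 s on one
CPU): 60 calibrated phantoms (20 per class, 320×320, 30 alveoli each) for
trend and classifier checks; 30 phantoms for segmentation
precision/recall/area-error; constructed two-circle and hexagonal scenes
for wall geometry; a 20/20/14 split for the balancing count check (→ 60
rows). Thresholds (precision/recall ≥ 0.9, area error ≤ 15%, wall oracles
within 10%, classifier median accuracy ≥ 0.77) are fixed targets, not tuned
quantities.

## 9. Known limitations

* Phantoms use axis-aligned ellipses and stationary speckle; real alveoli
  are irregular and imaging artifacts are depth-dependent.
* Color ground truth places colored pixels independently; real
  birefringence hues are spatially coherent.
* Wall thickness is measured between lumens along 16 fixed directions;
  heavily anisotropic walls may need more rays (`SegmentationParams.n_rays`).
* The classifier is validated on synthetic data only; applying it to real
  images requires recalibrating segmentation parameters (top-hat radius,
  speckle floor) to the imaging resolution.
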