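# Methods

This note documents the models, algorithms, defaults and design choices
behind `numprops`, in the order the pipeline runs them.

## Stimulus generation (`stimgen`)

A stimulus is a pair of dot arrays compared for numerosity.  Dots are hard
discs with continuous centers on an integer pixel grid (origin top-left,
x rightward, y downward), placed by rejection sampling so that boundary
distance between any two discs is at least `min_gap`, and every disc lies
fully inside its panel.

**Radius solving.**  `solve_radii(n, A, dispersion)` returns `n` radii with
Σπr² = A exactly: a common base radius √(A/nπ), multiplied by uniform
factors in [1−d, 1+d], then rescaled.  Dispersion d (default 0.3) gives
heterogeneous dot sizes; d = 0 gives homogeneous arrays.  Budgets too small
for the minimum radius (2 px) raise an explicit error.

**Area conditions.**  The five built-in designs control total dot area per
array: `equal_total` (both arrays share one budget), `equal_mean` (equal
mean dot area, so totals scale with counts), fixed total-area ratios (2:1,
1:1, 1:2, 2:3, 3:2, larger-count array : smaller-count array), and
`approx_1_1` (ratio drawn uniformly in [0.96, 1.04]).

**Pixel-area calibration.**  Downstream analyses measure areas as *pixel
counts* of the rendered discs, and center-in-disc rasterization of an
analytic radius carries O(r) per-dot noise — enough to push a pair's
total-area ratio off its design value by a few tenths of a percent.  After
placement, each array's radii are therefore rescaled by a single factor
chosen by bisection so the summed pixel count hits the analytic target
(tolerance 0.2%, typically exact).  Placement reserves 15% fractional
radius head-room (`radius_margin`) so the upscaled discs can never overlap
or leave the panel.  This makes the extractor-verified area conditions hold
at better than 0.5% for every generated pair.

**Defaults.**  Panel 400×400 px; total-area budget 8000 px² for the
reference array (≈10.5% ink coverage at the 2:1 condition's maximum; only
between-array ratios matter downstream); `min_gap` 2 px, which under
8-connectivity guarantees discs never merge during segmentation (any two
pixels of different discs are > √2 apart); 10 000 placement attempts per
layout with up to 20 layout restarts.  Panel size and area budget are free
parameters of the designs — the printed designs fix counts, count ratios
and area *ratios*, not absolute sizes.

**Design tables.**  Counts and ratios follow the five printed designs
exactly (see README).  Where a design leaves freedom, the generator chooses
once: style-1 count pairs are drawn uniformly from the full rational grid
n_large/n_small ∈ [1.12, 2.00] with counts in [5, 32]; style 3 splits its
138 pairs 46/46/46 across the three area conditions (balanced design);
style-4 count ratios reuse the style-1 grid restricted to [5, 16]; style-5
color-count ratios cycle through the realizable count pairs of each printed
ratio.  Identical seeds give identical designs, layouts and byte-identical
PNGs.

**Rendering.**  A pixel belongs to a dot iff its center lies inside the
disc — no anti-aliasing, so segmentation is exact and reproducible.
Two-array styles render one grayscale image per panel; mixed-color styles
render one RGB image.  The stimulus list CSV records STIMID, style, file
names, counts, area condition and seed.

## Behavioral simulation (`behavior_sim`)

The simulator exists to give the preprocessing and validation stages input
with the statistical structure they assume: accuracy that follows Weber's
law in the dot ratio.  The linear ANS form

p = 1 − ½·erfc(|n1 − n2| / (√2 · w · √(n1² + n2²)))

is the standard one-parameter model of ratio-dependent discrimination
(noisy magnitudes with scalar variability w).  It is a simulation-only
choice, not a claim about any particular participant population.

Trials are one per participant × stimulus.  ERR ~ Bernoulli(1 − p) at the
participant's w; RT = rt_base + rt_ratio_slope·(n_small/n_large) + additive
log-normal noise (median 60 ms), truncated to [150, 5000] ms — the upper
bound mirrors a 5000 ms response window, the lower an anticipatory-response
floor.  Participant Weber fractions are log-normal around a configurable
median (default 0.25, log-SD 0.35), a realistic adult range spanning about
a factor of two.  `inject_outliers` multiplies a chosen fraction of
participants' RTs to exercise the exclusion rule.

`WeberModel` fits w by maximizing the binomial likelihood of per-stimulus
accuracies (bounded 1-D search on [10⁻³, 5]); the standard error comes from
the observed information (central-difference second derivative).  Data at
chance or at ceiling push the estimate to a bound and raise a warning.
Parameter recovery at 200 participants × 120 stimuli is within a few
percent of the generating value (tested at 15% tolerance).

## Property extraction (`features`)

**Segmentation.**  Foreground = pixels differing from the background (the
modal pixel value; dots are sparse).  Components are 8-connected.  Mixed
two-color images are partitioned by exact foreground color; more or fewer
than two foreground colors is an error.  Panel pairs are segmented per
image (or at a recorded split line).

**Geometry.**  Per component: area = pixel count; equivalent radius
r = √(area/π); perimeter = 2πr.  Using the circle-model perimeter rather
than boundary-pixel counting makes perimeter ratios exactly equal diameter
ratios (2πr₁/2πr₂ = r₁/r₂) and removes rasterization noise.  Centroid =
pixel mean.  Pairwise distances are Euclidean centroid distances over all
C(n,2) pairs; single-dot arrays have undefined distance statistics
(propagated as missing).  The convex hull is taken over *all* dot pixels
(the smallest contour containing the dots, not just their centroids), area
by Qhull; degenerate collinear sets return 0.  Density indices are
hull/n and hull/total-area.  SDs are population SDs (÷n) by default,
switchable to sample SDs via `ddof`.

**Feature vector.**  dot_ratio = min(n)/max(n).  Every visual index is the
fewer-dot array's value divided by the more-dot array's, so the vector is
invariant to input order.  Equal-count pairs (possible only outside the
printed designs) fall back to input order with a warning and dot_ratio 1.
Zero or missing denominators yield missing values, never ±inf.

**Hashes.**  All three hashes are 64-bit, computed on the grayscale
image, with bits defined by strict `>` against the reference statistic
(ties → 0) and the lower median for even counts — deliberate, because
binary dot images are tie-heavy.

* average hash: area-average (box) downsample to 8×8; bit = pixel > mean.
* DCT hash: downsample to 32×32, orthonormal type-II DCT, keep the
  top-left 8×8 low-frequency block, threshold at its median.  A DCT on the
  8×8 downsample itself would leave no low-frequency block to select, so
  the conventional 32×32 → 8×8 scheme is the default; the literal 8×8
  variant is available as `literal_8x8=True` (`--phash-literal-8x8`).
* wavelet hash: one-level 2-D Haar DWT of the 8×8 downsample; all 64
  coefficients (approximation + the three detail subbands) thresholded at
  their median, so both low- and high-frequency information contribute.

Hash dissimilarity is the Hamming distance between the hashes of the two
*array* images of one stimulus — for mixed-color styles, between the two
color-isolated renderings — the only reading that yields one value per
stimulus row.

## Behavior preprocessing (`behavior_prep`)

Outlier exclusion is a single pass at the participant level: compute each
participant's mean RT (correct trials only by default, matching the RT
outcome definition), then exclude participants outside mean ± 3 SD of the
distribution of those participant means within the dataset.  The
trial-level reading (pooled trial RT distribution as reference) is
available via `level="trial"`.  Iterated trimming is deliberately not done:
it would silently change n.  Fewer than three participants disables
exclusion with a warning.

Aggregation per stimulus: mean_err = mean of ERR over all trials;
mean_rt_correct = mean RT over correct trials (missing when a stimulus has
none, row retained); participant and correct-trial counts recorded.

## Validation statistics (`stats`)

Correlations are Pearson r with two-sided t-distribution p-values
(df = n − 2), pairwise-complete.  Single regressions are OLS with
intercept; R² and the model-F p-value are reported.  Hierarchical ΔR² fits
the nested pair (control; control + dot ratio) and tests the increment with
F = ΔR² / ((1 − R²_full)/(n − p − 1)) on 1 df — numerically identical to
the squared t of the dot-ratio coefficient.  ΔR² is clipped at 0 (nesting
guarantees non-negativity up to float error).  A control collinear with the
dot ratio returns ΔR² = 0 with a warning.  Missing cells are dropped
listwise per model with per-model n reported; RT models drop only rows with
missing RT.

The pooled hierarchical analysis adds k−1 dataset indicator variables to
both nested models; results are invariant to the reference level.
Bonferroni families are fixed at 75 (correlations: 15 properties × 5
datasets), 80 (single regressions per outcome: 16 × 5) and 75
(hierarchical per outcome) in paper mode; generic mode recomputes the
family from the grid actually run.  Two-sided classical tests throughout.
Outputs are tidy CSVs plus grayscale heatmaps (darker = larger magnitude)
and a run log stating family sizes and thresholds.

## What the synthetic data do and do not show

The generator reproduces the printed *designs* (counts, ratios, area
conditions) but not the deposited images themselves: absolute dot sizes,
panel geometry and layouts are this package's own defaults.  The simulator
produces behavior driven *only* by the dot ratio through the ANS model plus
RT noise — no visual-property influence on responses.  Consequently,
passing tests demonstrate that the machinery is correct (properties are
extracted exactly, the statistics obey their identities, ratio-driven
signal is detected and correctly attributed), and that structurally
expected patterns emerge (e.g. total distance correlates ≈0.9 with dot
ratio because spreading more dots in a fixed panel adds pairwise
distances).  They do not certify numerical agreement with any particular
deposited dataset's correlation or R² tables, which depend on the original
stimuli and participants.

## Problem sizes and numerical choices

Default runs use 200 simulated participants per dataset and the printed
set sizes (120/36/138/100/100); a full five-style pipeline completes in
well under a minute on one CPU.  Bisection tolerances: radius calibration
45 iterations on [0.85, 1.15]; Weber MLE xatol 10⁻⁶.  Random streams are
NumPy `default_rng`; the pipeline derives independent per-stage seeds from
the run seed via `SeedSequence`, so every output (including PNG bytes and
the MANIFEST hashes) is reproducible from the seed alone.

## Known limitations

* Dots are perfect discs; no occlusion, luminance calibration or
  anti-aliased rendering.
* The behavioral model has no visual-property, age or gender effects;
  hierarchical ΔR² on simulated data therefore reflects property–ratio
  collinearity, not perceptual interference.
* Hash bits on near-binary images are tie-heavy; different tie conventions
  (strict vs non-strict, lower vs upper median) would shift absolute
  Hamming distances, though not their qualitative near-zero correlation
  with the dot ratio.
* The style-1 "equal total area" condition does not additionally constrain
  mean area (and vice versa); whether within-array dot areas are
  homogeneous is governed by the `dispersion` parameter.
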