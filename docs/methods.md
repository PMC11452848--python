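# Methods

## Scene model and synthetic data

A grading rig photographs one fruit lying on the light backdrop of a
weight sensor, so every frame has three intensity populations: bright
background, a darker shadow band, and the fruit. The generator renders
exactly that and nothing more:

- **Fruit**: the inclusive lattice ellipse `((r−cr)/a)² + ((c−cc)/b)² ≤ 1`
  in row-major, 0-based coordinates, filled with a single RGB color.
- **Shadow**: the same ellipse translated down by `shadow_offset_px` rows
  (default 6), minus the fruit — a crescent — filled with
  `background_level · (1 − shadow_darkening)` (defaults 235 and 0.08, so
  shadow gray ≈ 216). This is the simplest geometry that produces a third
  intensity cluster.
- **Noise**: i.i.d. Gaussian per channel (default sd 4 gray levels),
  clipped to [0,255] and rounded — a plain additive model of camera noise.

Populations draw fruit color from a clipped normal, and radius (one value
for both semi-axes, so population fruit are circular) and weight from
normals truncated positive. Per-grade parameters live in YAML presets;
the four shipped species are synthetic constructions, not calibrated to
real produce, with adjacent grade means roughly 3 pooled SDs apart in at
least color, size or weight so that the default benchmark is sharp.
Lemon colors are kept dark enough (gray < 180) that the default 0–185
threshold band still segments them; genuinely light fruit on a light
background is a known failure mode of band thresholding.

What the generator does **not** emulate: surface texture and gloss,
blemishes and defects, perspective and lens distortion, uneven
illumination, and color gradients across the fruit. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
behavior under the stated model, not performance on real produce.

One detail is deliberate: preset and randomly sampled semi-axes avoid
near-integer values (fractional part in [0.25, 0.75] in
`sample_fruit_spec`). A discrete ellipse with a near-integer semi-axis
ends in a one-pixel tip that a 3×3 morphological opening removes; with
off-integer axes the rendered boundary is everywhere ≥ 3 pixels wide and
noise-free masks survive opening/closing unchanged, which keeps the
"segmentation recovers the exact rendered mask" invariant meaningful.

## Color measurement

`n_points` pixels (bounds 5–25, default 15) are drawn uniformly without
replacement from the fruit mask and averaged per channel; averaging
reduces the camera-noise error on each channel to `noise_sd/√n`. The
derived features are chromaticities `r+g+b = 1`, intensity
`I = (R+G+B)/3`, saturation `S = 1 − min/I` (scale-free; clamped to
[0,1] against one-ulp overshoot), and the geometric hue

    θ = arccos( 0.5((r−g)+(r−b)) / (√((r−g)² + (r−b)(g−b)) + ε) ),
    θ ← 2π − θ if b > g,    H = θ/2π,    H = 0 when S = 0,

with ε = 2.22·10⁻¹⁶ (double-precision machine epsilon) guarding the
achromatic denominator. The square root in the denominator is required
for the arccos argument to stay in [−1,1]; without it the expression is
not a cosine. Black input (R+G+B = 0) gets chromaticities (0,0,0), S = 0,
H = 0 and a flag. Hue is intrinsically discontinuous at the achromatic
axis; property tests stay clear of S ≈ 0.

## Segmentation

Gray conversion uses BT.601 luminance weights (0.299, 0.587, 0.114),
rounded half-up to uint8. Foreground is the inclusive band
`lower ≤ p ≤ upper` (defaults 0/185): the fruit is darker than the
backdrop. Otsu mode replaces the upper bound with the level maximizing
between-class variance `w₀w₁(μ₀−μ₁)²` over all 256 splits, ties broken
toward the smallest level. Hole filling flips background components not
connected to the border (4-connected background flood, complementing
8-connected foreground); cleanup is opening-then-closing with a 3×3
square. Both are idempotent. Size is reported in pixels only — no
millimeter calibration is possible without camera geometry.

`cluster_intensities` is a 1-D k-means (default k = 3) with
deterministic initialization at the k centered quantiles
`(i + 0.5)/k` of the sorted intensities — reproducible without random
restarts — convergence when the largest mean shift is below 10⁻⁴ gray
levels (max 100 iterations), emptied clusters re-seeded at the intensity
farthest from the surviving means, and per-cluster population variances
reported. It is exposed as a diagnostic/alternative segmentation; the
grading chain uses the threshold route.

## Grading

Reference statistics use the population variance (divisor n), matching
the small-sample calibration style of the rig (default `n_reference` =
10 fruit per grade). The per-feature plausibility range is `x̄ ± Var`
(note: the variance, not the SD — the range is a reported diagnostic,
not a classifier). Distance denominators are the per-grade standard
deviations by default, making every term a squared z-score and the
distances unit-free and scale-invariant; `scale_mode="variance"` divides
by the raw variance instead for users who want the literal alternative.
Scales are floored at 10⁻⁶ feature units so constant training features
cannot divide by zero. `d` in the Q formula is the square root of the
summed squared terms.

Classification is argmax over `Q₁..Q₄` with ties to the lowest grade
index. A pure in-range rule (accept a grade iff `Qmin ≤ Q ≤ Qmax`) can
leave fruit unassigned or multiply assigned when bands overlap, so band
membership is demoted to a reported flag. Color enters as channel means
by default; `color_mode="chromaticity"` switches to (r,g,b). Equal
weighting of the three exponential terms is the default; the feature set
and weights are the natural place to specialize per species.

## MLP grader

The network consumes the full standardized 11-feature vector (R, G, B,
r, g, b, H, S, I, size, weight); z-scoring uses training-split means/SDs
with the SD floored at 10⁻⁸ so constant columns become zeros. Defaults —
one hidden layer of 10 logistic units, SGD with momentum 0.9, learning
rate 0.01, 500 epochs, seeded initial weights — are deliberately modest:
the network completes the pipeline as a second grader, it is not tuned
for maximum accuracy. Training is scikit-learn's `MLPClassifier` under
the hood with early stopping disabled so the full epoch budget always
runs, keeping identical seeds bit-reproducible. Models serialize to JSON
(weights, config, standardization constants).

## Evaluation

TP/FP/TN/FN are defined one-vs-rest per grade on the 4×4 confusion
matrix (rows = real class, columns = anticipated class). Overall
accuracy is the micro average `trace/total`, which equals the
sample-weighted mean of per-grade sensitivities. Four example confusion
tables for tomato/apple/lemon/peach sorters ship as CSV package data;
their derived accuracies (95.0, 72.5, 91.18, 88.75%) follow from their
counts by this arithmetic.

## Pipeline and reproducibility

An end-to-end run splits the dataset stratified 50/50 (seeded), fits
grade references on the first `n_reference` training fruit per grade,
fits Q bands on the whole training split, trains the MLP on the whole
training split, and evaluates both graders on the held-out fruit. Every
random draw — rendering, sampling, splitting, weight initialization —
descends from one integer seed via spawned `SeedSequence` streams, logs
carry no timestamps, and the run manifest pins config and library
versions, so reruns are byte-identical.

Default benchmark sizes (100 fruit per grade at 120×160 px for the
separation study; 10,000 pixels for the mixture-recovery check; 10,000
triples for the HSI cross-check) keep a full test-plus-acceptance cycle
in well under a minute on one CPU while leaving Monte-Carlo margins
(binomial SE ≈ 1.5 percentage points at n = 200) far smaller than the
effects being demonstrated.

## Known limitations

- The generator's flat-colored ellipse is a deliberately minimal fruit;
  nothing here validates performance on real images.
- Band thresholding fails for fruit whose gray overlaps the backdrop's;
  only the Otsu option and the clustering diagnostic address that, and
  only partially.
- Grade assignment assumes exactly four grades; the confusion-matrix
  tooling is likewise fixed at 4×4.
- Hue near the achromatic axis is ill-conditioned (any hue value is
  "correct" for gray); downstream use of H should weight it by S.
- The Q score treats color/size/weight as independent; correlated
  features (e.g. size and weight) are double-counted relative to a
  Mahalanobis treatment.
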