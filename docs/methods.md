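# Methods

## Problem setting

A trained object detector emits, per image, boxes with confidence scores.
For a reliability analysis these predictions must be (1) labelled correct or
incorrect against ground truth, (2) summarized by detection metrics and a
calibration error, and (3) remapped to calibrated confidences. `detcal`
implements that post-detection stack; it never trains or runs a detector.

## Correctness and matching

A prediction's correctness z ∈ {0,1} is defined operationally by matching:
detections below the confidence threshold are discarded; the survivors are
processed in descending confidence (ties by input order) and each greedily
claims the unmatched same-class, same-image ground truth with the highest
IoU at or above the IoU threshold (IoU ties go to the lowest ground-truth
index). Each ground truth can be claimed once; duplicates of an
already-claimed ground truth are false positives, unclaimed ground truths
false negatives. This is the standard COCO-style greedy protocol: it is
deterministic, auditable, and — as the test suite verifies against an
exhaustive assignment search on small scenes — almost always attains the
maximum possible TP count (greedy can underperform an optimal assignment on
contrived overlap patterns; the suite checks agreement on ≥ 95% of random
small scenes).

Two thresholds exist and are deliberately separate: the confidence cutoff
for counting a detection at all (default 0.4, a typical operating point for
reporting precision/recall/f1) and the IoU criterion defining correctness
(default 0.5, the conventional choice). Both are parameters everywhere they
appear.

Degenerate metric cases use the conservative convention precision = 0 when
TP+FP = 0, recall = 0 when TP+FN = 0, f1 = 0 when precision+recall = 0.

## Expected calibration error

ECE bins the confidence p̂ into M equal-width bins over [0,1] — the last bin
right-closed so p̂ = 1 is always counted — and averages the absolute gap
between per-bin precision (mean z) and per-bin mean confidence, weighted by
bin occupancy. Empty bins contribute zero. M defaults to 10, the dominant
convention in the calibration literature; ECE is monotone in nothing and not
comparable across different M, so M is always reported alongside. Only the
confidence is binned; box features influence the calibrator, not the error
measure, so a detector gets a single scalar ECE. With M = 1 the definition
collapses to |mean(z) − mean(p̂)|, which the tests assert exactly.

## Dependent logistic calibration

Feature vectors s of correct (z = 1, "+") and incorrect (z = 0, "−")
predictions are modeled as multivariate Gaussians. The calibrated confidence
is g(s) = σ(lr(s)) with

    lr(s) = ½[(s−μ₋)ᵀΣ₋⁻¹(s−μ₋) − (s−μ₊)ᵀΣ₊⁻¹(s−μ₊)] + c
    c     = ½·ln(det Σ₋/det Σ₊) + ln(n₊/n₋)

which is exactly the Gaussian class-posterior log-odds (QDA): when the
class-conditional densities really are Gaussian, g(s) → P(z=1|s). The prior
log-odds term ln(n₊/n₋) can be disabled (`include_prior=False`) to obtain
the bare density-ratio constant. When the two covariances are equal the
quadratic terms cancel and lr is affine in s — the LDA/logistic special
case; the implementation makes no such assumption.

Numerical choices:

- Means and covariances are sample estimates (covariance denominator n−1).
  Each population needs at least dim+1 samples; smaller populations raise a
  fitting error naming the deficient class.
- Each covariance is regularized by λI with λ defaulting to
  1e-6·mean-trace/dim — enough to guarantee positive-definiteness for
  near-degenerate populations without visibly perturbing the map.
- Mahalanobis terms are computed by Cholesky solves and log-determinants
  from Cholesky factors; no matrix is ever explicitly inverted.
- Confidence enters s logit-transformed by default, clipped to
  [ε, 1−ε] with ε = 1e-6: a Gaussian fits an unbounded score far better
  than one pinned to [0,1]. Raw mode is a flag. Box centers enter as
  normalized coordinates in [0,1] untransformed.
- One calibrator per class; with the single calcification class this is one
  model.

Calibration operates on predictions only: missed ground truths carry no
confidence and never enter the record stream.

The fit/test protocol splits the records 60/40 by seeded shuffle, stratified
by z by default (the z ratio is preserved within one record per stratum).

## Synthetic data: what it emulates and what it does not

The simulator stands in for a detector run on coronary OCT B-scans. Per
image it samples axis-aligned ground-truth boxes (uniform side lengths
60–220 px in a 1024×1024 image — roughly the scale of calcified regions in
a B-scan at ~2 µm/px); each is detected with probability 1 − miss_rate
(default 0.1) with Gaussian localization noise (default 8 px); spurious
detections arrive Poisson(1 per image) with low-mean Beta(2,4) confidences.
True-positive confidences follow Beta(5,2) — high-skewed, as post-threshold
detector scores are.

Two labelling modes:

- **iou_labeled** — z comes from the same IoU matching a real evaluation
  uses, so the full pipeline (files → matching → records → calibration) is
  exercised with realistic coupling between geometry and correctness.
- **posterior_driven** — z is drawn from a stated logistic truth
  P(z=1|s) = σ(a₀ + a_conf·logit(conf) + a_cx·(cx−0.5) + a_cy·(cy−0.5)),
  recorded per detection, giving an exact oracle. The default coefficients
  (a₀ = −1, a_conf = 0.5, a_cx = 2, a_cy = 0) produce an overconfident
  detector (stated confidence exceeds precision, before-calibration
  ECE ≳ 0.25) with position-dependent miscalibration, the regime that
  motivates feeding box centers to the calibrator.

All randomness flows through one `numpy.random.default_rng(seed)` stream, so
(config, seed) fully determines the dataset.

What passing tests on this stream shows: the estimator algebra is right
(ECE matches a brute-force oracle to 1e-12; lr matches the explicit
two-Gaussian density ratio to 1e-9), the calibrator recovers a known
posterior when its model is correct, and on a miscalibrated stream with a
logistic truth the fitted map removes most of the ECE, with the box-center
features measurably helping. What it does not show: that real OCT detection
features are class-conditionally Gaussian, that the miscalibration of a real
YOLO/SSD/Faster-RCNN on coronary data has this form or magnitude, or any
specific before/after ECE value for such models — those depend on the
detector and the data.

## Augmentation

Only two operators exist, matching what is physically valid for OCT:

- **Motion blur** — convolution with a normalized anti-aliased line kernel
  of odd length L (default 9 px) at angle θ (default 0°, measured CCW from
  the x-axis), rasterized on an L×L grid with linear falloff perpendicular
  to the line. Borders replicate edge values, so constant images are
  preserved to machine precision and interior intensity is redistributed,
  not lost. L and θ are free parameters; any normalized line kernel
  satisfies the invariants the tests pin down.
- **Horizontal flip** — pixel columns reversed, each box mapped to
  (W−x_max, y_min, W−x_min, y_max). An involution; exactly so for
  grid-aligned (dyadic) coordinates, to within one ulp for arbitrary reals.

Vertical flips and rotations are deliberately not implemented: OCT light
propagates in a fixed axial direction and such transforms would change the
nature of the image.

## Problem sizes and design notes

The test suite and acceptance script run everything at sizes a laptop
handles in seconds to a couple of minutes: ~50k-record streams (10 seeds)
for the calibration end-to-end checks, 50k samples per class for posterior
recovery, 100k records for the perfect-calibration null, 1000 small scenes
for the matching oracle. These sizes put sampling noise well below the
asserted tolerances (binomial error on a 10-bin ECE at N = 20k held-out
records is ~0.003).

Known limitations: the calibrator is parametric — if the class-conditional
feature densities are far from Gaussian (e.g., strongly multimodal), g(s)
converges to the best QDA posterior, not the true one; ECE inherits the
usual binning sensitivity; greedy matching is not a global optimum on
adversarial overlap patterns; the simulator emits box/score streams only,
not raster OCT phantoms.
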