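# Methods

## The measurement model

An autofluorescence image enters the pipeline as an 8-bit RGB raster
with a circular region of interest (ROI) marking the lesion. The RGB
raster is collapsed to one intensity channel either by the BT.601 luma
(0.299 R + 0.587 G + 0.114 B, the default) or by taking the G channel
directly; the emitted autofluorescence is green, so the two options
differ mainly in scale and both are exposed. ROI membership uses
0-based pixel centers with `x` the column, `y` the row, and the closed
disc `(x−cx)² + (y−cy)² ≤ r²`. The circle's center must lie on the
raster and the disc is clipped to the frame; a resolved region must
contain at least two pixels because the heterogeneity statistic uses
the sample (N−1) standard deviation. A region whose pixels are all
equal reports exactly zero spread (short-circuited before the
summation, whose round-off would otherwise produce ~1e−14 and defeat
degenerate-reference detection).

Normalization divides the ROI mean and standard deviation by the same
statistics of a reference region. Two references are offered: the
whole gray image (default, robust for small images) and the ROI
complement. The rationale is that bright non-ROI structures — teeth,
the device, prostheses, filling materials — both scatter light into
the ROI and vary between images; dividing by reference statistics
cancels multiplicative illumination exactly and tracks additive stray
light approximately. A degenerate reference (zero mean or zero spread,
e.g. a noiseless synthetic frame) is handled by policy: `error`
(default — silent substitution would corrupt features), `skip` (the
normalized vector is absent), or `epsilon` (substitute 1e−6).

## The classifier

Each class is a bivariate Gaussian fitted by moment estimators: class
sample mean, class sample covariance with the n_c−1 denominator (plus
an optional ridge `reg·I`, default 0), pooled covariance as the
(n_c−1)-weighted average of class covariances, and empirical class
priors (uniform or explicit priors available). These choices make the
algebraic collapse exact: replacing every class covariance with the
pooled one renders the quadratic and linear rules identical, which is
used as a test invariant. All densities and scores are computed in log
space via Cholesky factorizations; posteriors use log-sum-exp.
Prediction is the score argmax with ties broken toward the lowest
class index in the declared order N, M, PM (the table order). A
singular class covariance with zero ridge raises rather than being
silently repaired.

Decision grids label every node of a rectangular grid covering the
training features (default margin 10% per side). In LDA mode the
traced pairwise boundaries are straight lines up to grid quantization;
the test suite checks collinearity of boundary nodes at R² > 0.999 on
a 500-node-per-axis grid, where quantization noise is negligible.

## Evaluation

Confusion tables are oriented rows = actual, columns = predicted; the
per-class one-vs-rest decomposition gives TP (diagonal), FN (row
remainder), FP (column remainder), TN (the rest). Precision, recall
and F1 follow the usual definitions with a report-0-and-flag
convention for zero denominators; multiclass accuracy is trace/total.
Both macro (unweighted) and support-weighted averages are reported,
because two-decimal rounding in published tables does not
disambiguate which was used; support-weighted recall equals accuracy
identically and serves as an internal consistency check.

The stratified split assigns `floor(f·n_c)` of each class to training,
which reproduces the published 112/38 (tongue, 150 images) and 142/48
(buccal, 190 images) splits at f = 0.75. Stratified k-fold CV (k = 2
in the published protocol) is provided independently; how the original
analysis combined the 75/25 split with 2-fold CV is not stated, so the
pipeline uses the split for table generation and exposes CV
separately. The normalized and un-normalized branches share the same
split indices so their comparison is paired.

ROC curves are one-vs-rest threshold sweeps over the positive-class
posterior (the published analysis does not state its score function;
the posterior from the fitted discriminant is the natural choice and
the mode is recorded on the curve). Tied scores are grouped into
single steps, the curve is anchored at (0,0) and (1,1), and the AUC is
the trapezoidal integral — equal to the tie-corrected Mann–Whitney
statistic over n_pos·n_neg, which the tests verify pairwise. The
macro-average curve interpolates each per-class curve onto a common
101-point FPR grid (duplicate FPRs collapse to their maximum TPR) and
averages TPR pointwise.

## The synthetic cohort

The generator emulates the study conditions, not any particular
patient: three classes at two subsites, five-images-per-case counts
(tongue 55/55/40, buccal 50/100/40, 340 total), green-dominant
rendering (R and B at fixed 0.30 and 0.15 fractions of G), and
class-typical fluorescence patterns — N: FVR disc, M: FVL disc, PM: an
FVI annulus around an FVL core (core radius 0.55·r). Scene nuisances
are a per-image multiplicative gain U(0.65, 1.35), an additive ambient
stray-light offset proportional to the number of bright confounders
(1–3 discs/rectangles at intensity 235–255 placed strictly outside the
ROI, ambient 8–25 intensity units each), background noise of sd 3 and
within-ROI Gaussian noise whose sd is the heterogeneity parameter. Per
class, the ROI contrast and heterogeneity are themselves sampled per
image (N: shift +15…+45, sd 5–18; PM: rim +10…+40 over core −30…−5,
sd 8–22; M: shift −50…−15, sd 12–30), representing lesion-to-lesion
biological variation that normalization cannot and should not remove.

These defaults were chosen once so that the default cohort is
QDA-separable but not trivially linearly separable: un-normalized
features are degraded by gain and stray light (median test accuracy
≈ 0.79), normalized features recover most of it (≈ 0.96–0.97), and
the class scatters are heteroscedastic enough that QDA never trails
LDA. The noise stream is a single named per-scene generator with unit
draws scaled afterwards, so within-ROI spread is monotone in the
heterogeneity parameter over matched seeds and fixed seeds give
bit-identical images.

What the generator does **not** emulate: anatomy and texture of oral
mucosa, specular highlights, vignetting, fluorophore biochemistry
(NADH/FAD), camera response curves, or patient-level correlation
between the five images of one case (images are independent draws, so
split counts match the published image-level bookkeeping; a
patient-grouped split would be the conservative alternative on real
data). Passing tests therefore demonstrate the correctness of the
statistics and classifiers and the qualitative value of normalization
under these nuisances — not clinical performance. In particular the
published accuracy-gain percentages on clinical data are not
reproducible from synthetic scenes and are not asserted anywhere.

## Numerical and design notes

- The published description of the confusion-table orientation
  (rows = predicted) contradicts the printed per-class values, which
  are only consistent with rows = actual / columns = predicted; the
  numbers are followed and the prose treated as a typo.
- The printed multiclass "accuracy" formula contains a typo; accuracy
  is implemented as trace/total, which reproduces the printed
  percentages (99/112 → 88%, 120/142 → 84%).
- Exactly one printed performance entry is internally inconsistent
  with its confusion counts (tongue LDA un-normalized training
  recall(PM): printed 0.86, counts give 38/43 ≈ 0.88, and the printed
  F1 0.87 confirms 0.88); it is recorded in
  `velquant.datasets.KNOWN_INCONSISTENT` and excluded from exact
  recomputation checks.
- The normalization reference is ambiguous in the source description
  (a literal reading would make μ_N ≡ 1); both whole-image and
  ROI-complement references are implemented, defaulting to the whole
  image.
- Problem sizes in tests and the acceptance script: 96×96-pixel
  scenes, 150-image cohorts, 9–20 master seeds for medians, 10⁴
  samples/class for parameter recovery — small enough to run in
  seconds while leaving Monte-Carlo margins far from the asserted
  thresholds.

## Known limitations

- The LDA cross-check against scikit-learn is exact only for balanced
  classes: the pooled-covariance scalings differ (n−K vs n
  denominators), which with unequal priors can flip points within a
  thin boundary band.
- `epsilon` degenerate-reference handling produces extreme but finite
  ratios by design; downstream fits with such rows may need the ridge.
- The XLSX feature-table loader infers columns heuristically
  (intensity/sd/label by name, else the first three columns) and is
  intended for supplementary-style sheets only.
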