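# Methods

This note documents the model conventions, parameter choices and known
limitations of `scarvss`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Problem setting

A burn scar's Vancouver Scar Scale (VSS) total — the sum of pigmentation
(0–2), vascularity (0–3), pliability (0–5) and height (0–3) subscales,
maximum 13 — is treated as a class label to be predicted from a cropped
scar photograph. Each crop is divided into a 3×3 grid of equal sub-images
(floor-divided; bottom/right remainder pixels dropped) to multiply the
sample count; tiles inherit their parent's label. Only color and texture
enter the features; pliability and height are physically unobservable in
a 2-D photograph, which bounds attainable exact accuracy.

## Texture features

- **Quantization.** GLCMs are computed on 8 gray levels spanning
  `[min, max]` of each patch (equal-width bins, maximum maps to the top
  level, constant patch maps to level 1). The level count is configurable;
  8 is the common default of the numerical toolboxes used in this field.
- **GLCM.** Single offset (0, +1) — one pixel to the right — and
  non-symmetric counting; probabilities are counts over the total pair
  count n(h). All entropies use natural logarithms with 0·ln 0 ≡ 0.
  Degenerate denominators (σ_x σ_y = 0 for correlation, max(HX, HY) = 0
  for the information measure) yield 0 rather than NaN. Design choices
  within the 19-feature list: "information measures of correlation" is
  counted as the single feature IMC1 (IMC2 is available separately via
  `glcm_imc2`); sum variance is centered on sum average (the standard
  correction of the original formulation); "inverse difference" is
  implemented in its L-normalized form so it does not duplicate
  homogeneity.
- **Semi-variogram.** Computed on the unquantized 0–255 grayscale values,
  10 lags each in the horizontal then vertical direction. γ(h) is half
  the mean squared difference over all pairs at exact lag h, so it is
  invariant to adding a constant and scales quadratically with intensity
  scaling. The 10-lag default requires patch extents of at least 11
  pixels.
- **LBP.** V = 8 neighbors on a circle of radius R = 1; neighbor 0 lies
  due east, neighbors proceed counter-clockwise; off-grid positions are
  bilinearly interpolated, with coordinates within 1e-9 of an integer
  snapped so axis-aligned neighbors compare exact pixel values. The
  threshold convention is b(x) = 1 for x ≥ 0 (a constant patch yields
  code 255 everywhere). To make that convention numerically exact, the
  interpolation is applied to neighbor-minus-center differences rather
  than raw values, so equal pixels give a difference of exactly zero
  regardless of floating-point weight rounding. The descriptor is the
  full 256-bin normalized code histogram — no rotation-invariant or
  uniform-pattern mapping.

## Color features

Population (divide-by-N) central moments per RGB channel; kurtosis is
non-excess (Gaussian → 3); a constant channel is assigned skewness and
kurtosis 0. HSV and CIELAB conversions assume sRGB primaries and a D65
white point (no camera calibration is attempted). Histograms use 4
equal-width bins over fixed nominal ranges — H, S, V in [0, 1], L* in
[0, 100], a* and b* in [−128, 127] — with values clipped into range and
the last bin right-closed; fixing the ranges keeps features comparable
across images. Hue is binned as a linear quantity, a deliberate
simplification that ignores its circular topology.

## Feature assembly and standardization

Blocks are concatenated in the canonical order GLCM (19), SV (20),
LBP (256), RGB (12), HSV (12), LAB (12); the combined default
`(LBP+SV)+(RGB+HSV+Lab)` has 312 columns. Columns are z-scored over the
*entire* dataset with the sample (N−1) standard deviation before
cross-validation — the protocol this pipeline reproduces, and a known
mild leakage since held-out samples contribute to the column statistics.
A fold-wise option (`fold_standardize=True` in `loo_cross_validate`, or
`--fold-standardize` on the CLI) re-estimates the statistics per training
fold. Zero-variance columns are zeroed and flagged rather than dropped so
column counts are stable.

## ECOC classification

One-vs-one coding: columns enumerate unordered class pairs (i < j) in
lexicographic order with class i → +1 and class j → −1; K = 8 observed
classes give 28 binary learners, each trained only on its two classes.
Decoding minimizes `Σ_l |m_kl| g(m_kl s_l) / Σ_l |m_kl|`, with the hinge
loss `max(0, 1−z)/2` on signed margins (linear/RBF SVM, LDA) and the
Hamming loss `(1−sign(z))/2` on hard ±1 votes (1-NN, Gaussian naive
Bayes). With hard votes this reduces exactly to pairwise majority voting;
all ties resolve to the smallest class label, and 1-NN distance ties to
the earliest training sample — determinism is preferred where the
convention is otherwise arbitrary.

Learners: `knn1` (native 1-nearest-neighbor, Euclidean), `linear_svm`
(C = 1), `lda`, `gnb`, and `grid_svm` — an RBF SVM whose box constraint
C ∈ {0.01, 0.1, 1, 10, 100} and kernel width σ ∈ {0.1, 1, 10}
(γ = 1/(2σ²)) are selected by stratified 5-fold inner cross-validated
grid search. Grid search is this package's deterministic stand-in for
Bayesian hyperparameter optimization of the SVM and is flagged as such;
when a class has fewer samples than two inner folds the mid-grid model
(C = 1, σ = 1) is used directly.

Leave-one-out cross-validation trains N models on N−1 samples each. For
deterministic learners the procedure is invariant to sample order; the
seed only reaches stochastic internals such as the inner-CV shuffling of
`grid_svm`.

## Evaluation

Tolerance accuracy counts a prediction as acceptable when it is within
`tol` *positions* of the truth in the ascending list of observed classes
(not raw VSS score difference — the observed totals {0,1,2,4,5,7,8,9}
have gaps, and the position convention is the one under which the
packaged reference confusion matrices reproduce their published one- and
two-score tolerance accuracies exactly; the score-difference variant is
available as `mode="score"`). Percentages are rounded half-up to two
decimals. Two published 8×8 LOO confusion matrices ship as worked
examples (`reference_confusion("osvm_combined")` and `("knn_combined")`);
for the kNN matrix the printed exact accuracy in its source disagrees
with the matrix trace (81.19 % vs 170/216 = 78.70 %), so only its
internally consistent one- and two-score values are used as reference
numbers.

## Synthetic data

The generator emulates the study *design*, not scar photographs: each
class is a stationary colored random field
`base_rgb + amplitude·T + ε`, where T is Gaussian white noise smoothed
with a Gaussian kernel of width `texture_scale` pixels and rescaled to
unit variance (so `amplitude` is the texture contrast in intensity
units, 20–50 by default), and ε is per-channel white noise (sd 4).
Pixels are clipped to [0, 255]. Class difficulty is controlled by two
orthogonal knobs — base color and correlation length — so color-only and
texture-only feature combinations are each informative alone; a
`separation` parameter shrinks all between-class differences toward the
pooled mean for degradation experiments.

Default conditions follow the study design: 24 parents with class counts
(3, 9, 2, 1, 1, 5, 1, 2) over totals {0, 1, 2, 4, 5, 7, 8, 9}, each
150×150 pixels so the 50×50 tiles give stable 256-bin LBP histograms
(48×48 interior pixels) and comfortably support 10-lag semivariograms.
Texture scales span 0–3.5 px: correlation lengths much larger than that
leave too few independent texture patches per tile and make LBP
histograms erratic. Base colors are widely spaced across plausible skin
and scar hues. Fixed subscore decompositions (e.g. 9 = 2+3+2+2) make
each synthetic manifest internally consistent.

What passing the synthetic recovery test shows: the full chain —
generation, tiling, grayscale conversion, all six feature blocks,
standardization, one-vs-one ECOC, LOO, tolerance accuracy — preserves
class information end to end. What it does not show: performance on real
scars, whose within-class variability (lighting, pose, anatomy, camera)
the stationary-field model does not attempt to emulate.

## Numerical conventions and degenerate inputs

Grayscale conversion uses BT.601 luma weights (0.2989, 0.5870, 0.1140)
with round-half-away-from-zero. 16-bit sources map to 8 bits by integer
division of the full range (//257). Constant images are valid
everywhere: quantization level 1, zero semivariogram, LBP code 255,
GLCM entropy 0 and correlation 0 by the degeneracy conventions above.
Empty co-occurrence sets (no pixel pairs at the offset) raise an error
rather than returning an empty matrix.

## Problem sizes used in the checks

The test-suite oracle comparisons run on 100 seeded random 8×8 patches
(GLCM and LBP) and 12×12 patches (semivariogram — the smallest extent
supporting 10 lags); the end-to-end recovery check runs the default
216-sample study at three seeds with the 312-column combined features and
the 1-NN learner, plus one label-permutation control whose accuracy is
expected near the class-imbalance chance level Σ(n_k/N)² ≈ 22 %.

## Known limitations

- Absolute accuracies on the original patient photographs cannot be
  reproduced here; the packaged reference confusion matrices stand in as
  exact worked examples of the evaluation arithmetic.
- Dataset-wide standardization (the default, for protocol fidelity)
  leaks held-out information into column statistics.
- The GLCM gray-level count, symmetry convention, entropy base and the
  SVM kernel/decoding conventions are declared package defaults, not
  values inferable from published results.
- Anisotropic semivariogram models, rotation-invariant LBP variants,
  multi-offset GLCM averaging, feature selection and probability
  calibration are out of scope.
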