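# Methods

This note documents the models, the numerical choices, and what the
synthetic phantoms do and do not establish.

## Segmentation chain

The chain assumes DR-relevant structure (vessels, hard exudates,
microaneurysms) is *high-frequency* relative to the retinal background:
subtracting a 9×9 local mean from the histogram-equalized luminance
leaves exactly that structure. Choices the pipeline fixes:

- **Grayscale**: BT.601 luma (0.299, 0.587, 0.114) — the common imaging
  default for 8-bit photographic material.
- **Resize**: bilinear, forced square 512×512 with pixel-centre
  alignment and a half-sample symmetric boundary (scikit-image
  convention). Aspect ratio is intentionally not preserved: all images
  share one working geometry.
- **Histogram equalization**: 256 equal-width bins on [0, 1]; level k
  maps to CDF(k). The mapping is monotone and preserves histogram mass
  at bin granularity. Note this is rank-based: it amplifies whatever
  intensity variation dominates pixel mass, including sensor noise in
  flat regions — relevant to phantom design below.
- **Mean filter**: all-ones 9×9 mask divided by 81, replicate border
  padding, so constants are fixed points.
- **Subtraction**: negatives clipped to 0; the downstream threshold
  expects nonnegative intensities. The subtracted image is re-normalized
  to [0, 1] (min–max) before thresholding.
- **Ridler–Calvard**: start T₀ = 0.5 (half the dynamic range),
  convergence tolerance 1e−4, cap 100 iterations. If the start leaves
  one side of the split empty (all pixels on one side of 0.5) the
  iteration restarts from mid-range, after which both sides are provably
  nonempty for non-constant input; the threshold is therefore strictly
  interior. A constant image returns the constant itself, flagged
  degenerate.
- **Binarization** is inclusive (pixel ≥ T → white). **Cleanup** removes
  8-connected white clusters of ≤ 50 pixels — 8-connectivity is the
  permissive choice for thin elongated vessel fragments.
- **Overlay** keeps grayscale values on the cleaned foreground and zeroes
  the rest; the complemented mask is produced as a display artifact only.
- **Degenerate inputs**: a constant-colour image has an identically zero
  subtracted image; any threshold splits it degenerately, so the chain
  short-circuits to an empty mask rather than marking the whole frame
  foreground.

## Texture statistics

The co-occurrence matrix uses a single displacement (0, 1) at distance 1,
non-symmetric, with 8 quantization levels (equal-width bins of [0, 1];
the maximum maps to the top level). Both the displacement and the level
count are exposed as parameters; 8 levels keeps the matrix well-populated
on 512×512 segmented images. Background zeros are counted: the statistics
describe the segmented image as a whole, and callers who want
lesion-only texture can mask beforehand.

The ten statistics are contrast, energy, entropy (natural log, 0·ln 0 :=
0), homogeneity, correlation, RMS, skewness, kurtosis, GLCM mean and GLCM
variance. Conventions that needed fixing:

- The marginal spread terms σᵢ, σⱼ used by correlation are *standard
  deviations* (square roots of the level-weighted second central
  moments); with variances instead, correlation would not be bounded by
  [−1, 1] and the coupled/anticoupled diagonal matrices would not map to
  ±1.
- Skewness is the third standardized moment of the N² matrix entries,
  mirroring the kurtosis formula's structure (1/((N−1)σᵏ) Σ(P−μ)ᵏ with
  k = 3); RMS is √(Σ P² / (N−1)). Entry mean/SD are population moments
  over all N² entries.
- Statistics undefined at zero variance (correlation on a point-mass
  matrix; skewness/kurtosis on a uniform one) raise a dedicated error at
  the operator level; the feature-vector extractor substitutes the
  sentinel 0 with a warning so feature tables stay rectangular.

## Classifiers

- **Scaling**: per-column linear map sending the training minimum to −1
  and maximum to +1; constant columns map to 0. The scaler is fitted on
  training folds only and applied unchanged to test rows (which may fall
  outside [−1, 1]); fitting on the pooled data would leak test
  information into the fit.
- **SVM**: polynomial kernel, C = 1, γ = 1, degree 3, coef0 = 1 (degree
  and offset are conventional defaults, exposed as parameters). The raw
  decision value w·x + b is used directly as the ROC ranking score — AUC
  is rank-based, so no probability calibration is needed.
- **DNN**: widths 10→1024→512→256→128→64→1; each hidden block is dense +
  ReLU, inverted dropout (rate 0.5), then batch normalization (momentum
  0.95, epsilon 0.001; running statistics used at inference and excluded
  from the trainable count). Loss is binary cross-entropy on the sigmoid
  output, computed from logits for numerical stability; optimizer is
  Adam (learning rate 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch size
  32, 100 epochs. Initialization is He-normal for ReLU layers and
  Glorot-style for the output. One seed controls weight initialization,
  batch shuffling and dropout masks, so training is bit-reproducible.
  The whole network, including backward passes, is implemented in NumPy.
- Parameter accounting is closed-form: a dense layer n_in→n_out has
  n_in·n_out + n_out parameters, batch norm over w channels has 4w (2w
  trainable), dropout none. The default stack totals 716,545 parameters,
  712,577 trainable.

## Evaluation

Stratified k-fold (k = 10) with shuffling; on a balanced 560-row table
every test fold has 56 rows, 28 per class, and every training partition
504. Hard labels use the inclusive rule score ≥ threshold (0.5 for
sigmoid scores, 0 for SVM decision values). AUC is the Mann–Whitney pair
statistic with ties counted half, which equals the trapezoidal area under
the empirical ROC; per-fold SDs are sample SDs (ddof = 1). Undefined
per-fold metrics (e.g. precision with no positive predictions) are
recorded as missing with a warning and excluded from the mean/SD. The
mean ROC is vertical averaging of per-fold curves over a fixed 101-point
FPR grid, pinned to (0,0) and (1,1).

## Phantom design

The phantom reproduces the photometric features the segmentation chain
relies on, not retinal anatomy:

- a bright disc (peak 0.75–0.82) with quadratic radial falloff on a dark
  (0.04) surround;
- 6–10 tortuous radial vessels, drawn as a dark body (10–18% of local
  background) with a 1-px **central light reflex** at the local
  background intensity — the thin bright stripe real vessels show along
  their axis. After mean subtraction the reflex is a strong, *connected*
  positive deviation sitting exactly on the recorded centreline, which is
  what makes the ≥ 80% skeleton-recall property hold robustly;
- for the DR class, 6–10 exudate clusters of 30–60 small bright specks
  (radius 1.5–3 px, intensity above the 90th percentile of the disc
  interior) plus 15–30 microaneurysm-like dots. Specks carry a
  yellow-white colour cast (green weight 0.90 vs the retinal 0.55), as
  hard exudates do, which places their luminance in gray-level bins that
  healthy phantoms never populate — the lesion load is typical of a
  screening-positive eye and makes the two classes texturally distinct
  by construction;
- additive Gaussian sensor noise (SD 0.02), clipped to [0, 1].

All randomness flows from one master seed through counter-based
`SeedSequence` spawning, so any subset of a dataset regenerates
identically.

**What passing phantom tests shows — and does not.** The end-to-end
checks (10-fold SVM AUC ≥ 0.85 on 60+60 phantoms; chance-level AUC after
label permutation) demonstrate that the implemented operators compose
correctly and that the texture features carry exactly the class signal
built into the images. They say nothing about performance on real fundus
photographs: phantoms lack optic disc and macula, pigmentation and
illumination variation, haemorrhages, camera artefacts, and the full
range of DR severity. The synthetic Gaussian feature tables used for
classifier unit tests (class means separated by Δ·σ on all ten columns)
likewise only calibrate the training and evaluation machinery.

## Problem sizes

Default experiment sizes were chosen so the full suite runs comfortably
on a single CPU: 60 images per class for end-to-end phantom evaluation,
200 per class for the Δ = 3σ DNN convergence check, 10 random ≤16×16
images per offset batch × 50 batches for the GLCM oracle, 100 random
score vectors for the AUC oracle. The fold count, network architecture
and training configuration are never scaled down.

## Known limitations

- The chain segments all bright high-frequency structure jointly; there
  is no vessel tracing, optic-disc localization or lesion typing, and no
  severity grading.
- Ridler–Calvard assumes a roughly bimodal subtracted-intensity
  histogram; on images with no high-frequency content the degenerate
  empty-mask path is taken.
- The single-displacement GLCM is direction-sensitive; rotating an image
  90° changes the features. Multi-angle averaging is deliberately out of
  scope.
- The NumPy DNN is single-threaded and intended for feature-table scale
  (hundreds of rows), not image-scale inputs.
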