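# Methods

`radpheno` implements an MRI-radiomics pipeline that predicts the spatial
immunophenotype of a breast tumor — *immune-desert*, *immune-excluded* or
*inflamed*, defined by where CD8+ T cells sit relative to the tumor margin
— from four post-contrast phases of dynamic contrast-enhanced (DCE) MRI.
Because the data that motivated the design are institutional and not
public, the package ships a synthetic phantom generator that plays the
role of the patient cohort; every end-to-end claim in the test suite is a
claim about those phantoms, not about patients.

## Pipeline

1. **Preprocessing.** Each phase volume is resampled to 1 mm isotropic
   voxels (linear interpolation for intensities, nearest-neighbour for the
   mask). No intensity normalization is applied: all texture features are
   computed on gray levels re-discretized per ROI, which makes them
   invariant to affine intensity rescaling. One whole-tumor mask, drawn on
   the subtraction image (second post-contrast minus pre-contrast), is
   shared by all four phases. The *tumor periphery* is the inner 2-mm rim:
   in-mask voxels whose Euclidean distance (in mm, using the voxel
   spacing) to the nearest out-of-mask voxel is at most 2 mm.

2. **Feature extraction.** A radiomic feature group (RFG) is the
   833-vector extracted from one ROI on one phase: tumor volume (mm³),
   64 texture features on the original image, and the same 64 on each of
   12 wavelet-filtered images. The 64-feature roster is 14 first-order +
   13 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM, the standard
   Haralick/Galloway/Thibault/Amadasun–King canon. Matrices are built in
   3D: 13 unique directions at distance 1 (GLCM pooled into one symmetric
   matrix; GLRLM features averaged over per-direction matrices), zones by
   26-connectivity, NGTDM neighborhoods the 26 surrounding in-mask voxels.
   Gray levels use fixed-bin-count quantization with G = 32:
   `level = min(G, floor(G(x - min)/(max - min)) + 1)`; a constant region
   maps to level 1 everywhere.

3. **Wavelet bank.** Three families (db2, coif1, sym4) × four
   low-frequency weights ("ratios" 1/2, 2/3, 3/2, 2) = 12 filtered
   volumes. A filtered volume is the inverse of a single-level 3D DWT
   (symmetric extension) in which the all-low-pass (LLL) sub-band is
   multiplied by the ratio and the seven detail sub-bands are untouched.
   This is the simplest band-weighting consistent with ratio values
   straddling 1, and it is exactly the identity at ratio 1, which anchors
   the tests. Other readings of "ratio" (e.g. per-axis weights) exist; the
   contract here is declared, not presumed universal. Each filtered image
   is re-discretized independently because its intensity range differs
   from the original's.

4. **Feature filtering.** Stability first: ICC(2,1) — single-rater,
   absolute agreement, from the two-way random-effects ANOVA
   `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` — is computed per
   feature over 20 patients segmented twice; features with ICC < 0.8 are
   dropped. ICC(2,1) rather than a consistency form because segmentation
   robustness demands absolute agreement. Then the surviving features are
   ranked by univariate AUC on the *training cohort only* and the top 50
   kept (all, when fewer than 50 survive). Ranking is direction-agnostic
   (max(AUC, 1−AUC)) by default — a feature with AUC 0.1 is highly
   informative — with a literal mode available. Ties break
   lexicographically on the feature name for determinism.

5. **Score models.** Two binary endpoints: *inflamed vs non-inflamed*
   from whole-tumor RFGs (all patients) and *desert vs excluded* from
   peripheral RFGs (non-inflamed patients only). Per endpoint and phase,
   an L1-penalized logistic regression (LASSO) is fit on standardized
   features (training mean/SD, stored for inference), with the penalty
   chosen at the minimum mean 5-fold stratified cross-validated deviance
   over a 16-point log-spaced grid (inverse penalty C in [1e-3, 10];
   weaker penalties are never CV-optimal on these problems and only slow
   the solver); the glmnet-scale penalty is reported as λ = 1/(C·n). The
   radiomic score is the linear predictor. If the CV-optimal penalty
   shrinks every coefficient to zero, the model degrades to an
   intercept-only constant score with a warning (the expected outcome on
   null cohorts, mirroring a penalized path at λ_max); the same contract
   applies to a feature-combined model whose input union is empty. A
   strict mode raises instead.

6. **Fusion.** The score-combined model (SC) refits the same LASSO on
   the four phase scores; the feature-combined model (FC) refits it on
   the union of features selected by the four phase models (phase-tagged
   names). Both re-select their penalty by the same CV protocol.

7. **Three-class caller.** Youden-optimal cutoffs (maximizing
   sensitivity + specificity over midpoints of sorted unique training
   scores; ties → lowest) are fitted on training scores of the two FC
   models. A patient is called *inflamed* if the whole-tumor score
   reaches its cutoff; otherwise *excluded* if the peripheral score
   reaches its cutoff; otherwise *desert*. Score orientation is pinned by
   construction: the whole model is trained with inflamed = 1 (its score
   correlates positively with central CD8 density) and the peri model
   with excluded = 1 (positively with peripheral CD8 density).

8. **Evaluation and statistics.** Validation-cohort confusion matrix,
   accuracy, per-class and macro-averaged F1 ("average F1" is read as the
   macro average). Model AUCs are compared pairwise with the paired
   DeLong test on the entire cohort — where the paired comparison has
   its full power — with Holm adjustment within each
   endpoint's family of nine comparisons (SC and FC vs each phase, FC vs
   SC). Two-group comparisons default to Welch's t-test (a pooled-variance
   Student option exists); three groups use one-way ANOVA with Tukey HSD.
   All tests are two-sided.

## Leakage discipline

Validation patients influence nothing fitted: ICC uses only the
duplicate-segmentation subset (no labels at all), AUC ranking,
standardization, penalty selection and cutoffs see training rows only.
The 3:1 split is stratified by phenotype with largest-remainder
allocation (182 → 137/45; every class within one patient of 3:1), and is
reproducible from its seed.

## The phantom generator

Each patient is an ellipsoidal tumor (radius 6–10 mm, axes jittered
±15%) centered in a 44³ volume at 1 mm isotropic spacing, over a smooth
noisy background (baseline 100, amplitude 4, correlation 4 mm), imaged
pre-contrast and at four post-contrast phases with wash-in factors
(1.0, 0.94, 0.86, 0.78) at enhancement 80 and additive Gaussian noise
(SD 4). Phenotype is encoded as spatially localized speckle (smoothed
white noise, unit variance, scaled):

| phenotype | core amp | rim amp | core corr. (mm) | rim corr. (mm) | kinetic loading |
|-----------|----------|---------|-----------------|----------------|-----------------|
| desert    | 0.45     | 0.30    | 1.0             | 1.4            | 0               |
| excluded  | 0.45     | 1.00    | 1.0             | 1.0            | 0               |
| inflamed  | 1.00     | 1.00    | 0.68            | 0.68           | 1               |

Amplitudes are multiplied by `texture_effect` (0.28) × enhancement ×
phase decay (1.0, 0.82, 0.66, 0.52), and the kinetic loading shifts the
enhancement by `kinetic_effect` (0.07) on the log scale. Desert and
excluded differ only in rim-localized parameters, so their contrast is
deliberately concentrated where the peripheral ROI looks.

The central calibration idea: every cue carries a per-patient, *per-phase*
log-normal jitter (amplitude SD 0.80 per phase vs 0.06 between patients;
correlation-length SD 0.40; kinetic SD 0.07) so that a single phase is a
noisy readout of the phenotype while averaging four phases recovers it
almost fully. This reproduces the qualitative pattern the method is built
around — moderate single-phase AUCs, near-excellent score- and
feature-combined models, and a first post-contrast phase that carries the
most texture signal. These defaults were fixed once, before the
acceptance suite was frozen.

CD8 densities (cells/mm²) are *generated covariates*, log-normal with
phenotype-specific means (central: 45/60/400 for desert/excluded/
inflamed; peripheral: 30/350/380; log-SD 0.5) — not derived from the
images — so score–density correlations arise only through the shared
ground-truth phenotype, which is exactly the inference the pipeline is
entitled to.

Duplicate segmentations add a smooth random field (amplitude 0.6 mm,
correlation 2 mm) to the signed distance of the mask and re-threshold;
voxel-center distances are recentered by half a voxel so the boundary
actually moves. On a 10-mm sphere this yields Dice ≈ 0.93–0.97 against
the original mask, within the intended 0.80–0.98 band of a careful
second observer.

**What the phantoms do not emulate:** MRI physics (coil inhomogeneity,
motion, partial volume beyond linear resampling), anisotropic acquisition
by default, non-ellipsoidal tumor shapes, inter-feature correlation
structures of real tumors, and any causal link between image texture and
immune biology. Passing tests show that the pipeline machinery — feature
mathematics, filtering, fitting, fusion, calling — recovers a phenotype
that is genuinely encoded in images under realistic noise, nothing more.

One intended design property is *not* realized: in the emulated tumors
the 2-mm rim is 50–70% of the tumor volume, so any rim-localized cue is
also visible to whole-tumor features; a "whole-ROI cannot see the
desert/excluded contrast" separation is geometrically unattainable at
these tumor sizes. The generator instead guarantees the contrast is
rim-localized *by construction* (tested structurally), and the peripheral
models remain the dedicated discriminators in the caller.

## Numerical choices

* ε = 1e−6 guards NGTDM and normalization denominators; a constant ROI
  yields coarseness 1/ε (documented cap), contrast/busyness/complexity/
  strength 0, GLCM correlation 1, first-order skewness/kurtosis 0,
  entropy 0, uniformity 1 — never NaN.
* GLCM is symmetrized and normalized after pooling all 13 directions;
  GLRLM features are averaged over per-direction matrices; both builders
  are verified against exhaustive brute-force enumeration.
* The saga solver runs at tolerance 1e−3 (penalty selection is
  insensitive well below this; verified against 1e−4) with a 10⁴
  iteration cap, seeded end to end: fold shuffling and solver shuffling
  both derive from the run seed, making reports bitwise reproducible.
* Tumor volumes and distances are physical (mm), never voxel counts.

## Problem sizes for the repeated-seed checks

The default end-to-end run uses the full default conditions (n = 182,
44³ phantoms). The repeated-seed robustness checks use scaled-down
cohorts chosen once: fusion-ordering seeds use n = 110 with prevalences
flattened to 0.35/0.30/0.35 (so the excluded arm stays estimable) and
30³ phantoms with 4–6 mm tumors. The fused-vs-single-phase ordering is
compared on entire-cohort AUCs, where the paired DeLong comparison has
its full power; split-validation AUC arms of 5–10 patients have null
sampling SD above 0.1, which makes strict per-seed inequalities there
uninformative.

The null-cohort overfitting guard follows the same logic: under the
null, a split-validation AUC over a 7-to-10-patient arm exceeds 0.7 by
pure sampling noise several percent of the time, so a "never above 0.7"
criterion on split validation is a coin flip at any affordable size.
The guard therefore extracts one 240-patient zero-effect cohort and runs
12 modeling replicates, each fitting the complete protocol (3:1 split,
ICC filter, top-50 AUC ranking, LASSO, fusion) on a random 90-patient
subset with permuted labels (exchangeable under the null) and scoring
the fused models on the ~150 held-out patients, where the null AUC SD is
about 0.04. Overfitting leakage, if any, would appear there directly.

## Known limitations

* The wavelet "ratio" semantics are a declared interpretation (see above).
* The 64-feature roster is a fixed, standard canon; no claim is made that
  it matches any particular clinical software feature-for-feature.
* λ at minimum CV deviance moderately overselects features (as it does in
  glmnet); no 1-SE rule is offered because the modeled protocol is
  explicit about λ-min.
* The three-class caller is a hard cascade of two thresholds; it emits no
  calibrated probabilities.
* With 1 CPU the full default pipeline run takes a few minutes; feature
  extraction dominates and scales with tumor voxel count.
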