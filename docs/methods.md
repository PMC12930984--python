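# Methods

This note documents the models and procedures implemented in `defaceqc`,
the defaults and why they were chosen, the numerical corner cases, and what
the synthetic-phantom validation does and does not establish.

## Preprocessing

Volumes are read from NIfTI and reoriented to RAS+ (right/anterior/superior)
before anything else, so "frontal" and the four oblique view directions are
well defined. Reorientation permutes and flips axes only; intensities are
untouched. Original and defaced volumes must share a grid — pairs come from
one acquisition, so a shape mismatch is treated as a data error, not a
resampling trigger.

Each volume is min–max normalized to [0, 1] independently (a constant volume
maps to all zeros rather than erroring, so degenerate fixtures flow
through). The head mask thresholds the normalized original at 0.03,
discarding low-intensity background noise. Two consequences of per-volume
normalization are worth knowing:

- A defacing tool that adds an *exactly uniform* offset to every voxel
  (including background) is invisible to the normalized volumetric features,
  because min–max normalization removes a global shift. The volumetric
  operations themselves detect it when applied to raw pairs (the simulator
  tests do exactly that); in practice scanner-scale perturbations are never
  perfectly uniform. Per-pair normalization (sharing the original's range)
  would be the alternative; per-volume was chosen as the simpler, more
  self-contained convention.
- "Completely removed" voxels are tested on normalized intensities
  (original ≠ 0 and defaced = 0), which coincides with the raw-intensity
  test whenever the volume minimum is 0 — true for all phantoms and for
  typical MRI backgrounds.

All head-relative percentages use the *original* scan's head mask as region
and denominator: the defaced scan's own head mask is itself altered by
defacing and would bias the denominator. An `altered_tolerance` ε (default
0) guards the impacted-voxel count against spurious float diffs introduced
by storage round-trips.

## Surface rendering

The five views are produced by orthographic first-hit ray casting rather
than a generic 3D visualization library: it is deterministic, dependency-
free, and a pure function of the data. Rays parallel to the view direction
(the facing direction +y rotated about +z by 0°, ±45°, ±90°) traverse the
grid at steps of half a voxel edge; the mask is sampled trilinearly and the
first sample at mask ≥ 0.5 counts as the surface hit. The pixel takes the
volume intensity half a voxel *beyond* the crossing, which reads the surface
voxel's value instead of the mask-boundary interpolation ramp (a uniform
cube therefore renders at exactly its intensity except on the one-pixel
footprint perimeter). Pixels with no hit are 0. The image plane spans the
volume bounding box, letterboxed square so pixels stay square; default
resolution 256×256 (tests use 64 for speed). No lighting model is applied —
the pixel value is data, not shading; a depth channel could be added but
similarity metrics on first-hit intensity already expose the surface
changes defacing makes. Rendering assumes near-isotropic voxels after
canonical reorientation; strongly anisotropic acquisitions would distort
aspect ratios.

## Similarity metrics

All four metrics operate on float renders in [0, 1], so the dynamic range
is L = 1 and the classical 8-bit constants are rescaled:

- **RMSE**, **PSNR** = 20·log₁₀(L/RMSE). PSNR of identical images is capped
  at 100 dB so the feature table stays finite for downstream classifiers;
  the cap also breaks the otherwise exact RMSE↔PSNR monotone relation only
  at identity pairs.
- **SSIM**: Gaussian window σ = 1.5 truncated at 11×11, C₁ = (0.01 L)²,
  C₂ = (0.03 L)², no sample-covariance correction, mean over the
  window-valid interior. Verified against scikit-image's implementation to
  1e-6.
- **FSIM**: phase congruency from a 4-scale × 4-orientation log-Gabor bank
  (smallest wavelength 6 px, scale multiplier 2, σ_onf 0.55, Rayleigh noise
  compensation with k = 2), gradient magnitude from the Scharr operator,
  per-pixel similarity S_PC·S_G with T₁ = 0.85 (phase congruency is
  scale-invariant, so T₁ needs no rescaling) and T₂ = 160/255² (gradients
  scale linearly with intensity), pooled with max(PC₁, PC₂) weights.
  Grayscale only — the renders carry no chrominance. Constant images have
  zero phase congruency everywhere; the pooled value is then defined as 1
  for identical inputs and the unweighted mean of S_L otherwise (which is
  also 1 for two featureless constants — there is no structure to disagree
  about). Verified against an independently structured reference
  implementation to 1e-3. Images must be ≥ 32 px per side.

Each metric is computed per corresponding view pair and aggregated by
arithmetic mean over the five views (a min-aggregation is available in
config for worst-view analyses).

## Classification protocol

Nested stratified group k-fold cross-validation, defaults k_out = 5,
k_in = 3 — conventional sizing for cohorts of a few hundred pairs. Fold
assignment is greedy: subjects (groups) are placed whole, largest first,
each into the fold that minimizes the dispersion of per-fold class shares,
with fold size as tie-break. This keeps folds near-equal, never splits a
subject, and tracks the global class balance as closely as whole-subject
assignment permits. Inner folds tune small fixed hyperparameter grids
(regularization strength for LR, hidden width for the MLP, tree depth for
RF/XGB) by mean inner AUROC; the winner is refit on the full outer-training
subset. The grids exist to exercise the nested protocol, not to squeeze
performance. LR and MLP get feature standardization fit inside each
training split; tree models use raw features.

The positive class is 1 = *insufficiently defaced*: a privacy failure is
the event sensitivity should refer to. Metrics (accuracy, sensitivity,
specificity, precision, AUROC at threshold 0.5) are averaged over outer
folds with their standard deviation; a single-class outer test fold yields
an undefined AUROC, recorded as missing, excluded from the mean, and
warned about.

Permutation importance is the mean AUROC drop over 10 (default) within-fold
permutations of one feature column, averaged across outer folds. Feature
selection iterates: cluster features by average-linkage on 1 − |Spearman ρ|
(cut at distance 0.2, i.e. |ρ| > 0.8), keep only the most important member
of each cluster, drop features below a 0.005 mean-AUROC-drop floor, refit,
and stop when a drop would lower the mean AUROC (reverting it), when
nothing is droppable, or after 10 iterations. Constant features have
undefined rank correlations; they are recorded as 0 with a warning so
clustering stays defined. The loop never eliminates the last remaining
feature. Exact duplicates merge at dendrogram distance 0 and lose one
member in the first iteration; their permutation importances are estimated
independently, so which member survives is effectively a coin flip.

Cohen's κ uses the closed form (p_o − p_e)/(1 − p_e) with p_e from the
raters' marginal products. p_e = 1 occurs only when both raters are
constant on the same label, where κ is defined as 1; a single constant
rater yields κ = 0 through the formula itself.

All randomness (fold seeds, permutation seeds, model seeds) derives from
one master seed via SHA-256-based sub-seeding, so every report is exactly
reproducible.

## Synthetic phantoms

The generator emulates the anatomy a defacing reviewer looks at: an
ellipsoidal head (default semi-axes 0.30/0.36/0.34 of a 96³ grid) with an
interior brain compartment (0.62 of the head's semi-axes, shifted slightly
posterior-superior; brain-to-head ratio ≈ 0.23) and four surface features —
nose, two eyes, mouth — as ellipsoidal protrusions on the anterior surface.
Intensities are piecewise constant (tissue 0.55, features 0.70, brain 0.85)
plus Gaussian noise of σ = 0.02 inside the head, clipped away from 0 so the
head mask stays exact; the background is exactly zero. Subjects share a
multiplicative shape jitter (±7%) across their scans, creating the
within-subject correlation that makes the group-fold constraint meaningful.

Simulated defacing spans the observed failure modes: per-feature removal
extent r ∈ [0, 1] applied surface-inward (a partial removal leaves a
realistic residual shell, and the removed set is nested in r, which gives
the monotone feature response the tests check); a tiny global additive
perturbation (default draw 0.001–0.004, more likely for the weakest
simulated method); and clipping of a random brain-mask fraction. Label
rules mirror the manual criteria: *strict* success requires every feature
removed to at least r = 0.95; *lenient* success tolerates one residual
feature if its removal extent is at least 0.5. The 0.95 and 0.5 cutoffs
operationalize qualitative review language ("complete removal", "minimal
residual trace") and are explicit configuration, not a claim about any
rater's internal threshold. Cohort generation assigns the requested number
of failures exactly (so a requested class balance is met to rounding),
distributing them across methods in proportion to per-method failure
propensities; labels are re-derivable from the manifest alone.

What the phantoms do **not** emulate: bias fields, k-space artifacts,
anatomical variability beyond affine jitter, partial-volume tissue
boundaries, or modality contrast differences (T1 vs FLAIR). Classifier
metrics on phantom cohorts therefore characterize the *pipeline* —
features respond to the right geometry, the protocol leaks nothing, chance
data scores at chance — and deliberately do not forecast accuracy on
clinical data.

## Problem sizes

The default API sizes (96³ grids, 256² renders) suit real data. The test
suite and acceptance script run phantoms at 32–48³ with 64² renders and
cohorts of 40–60 subjects (≈ 170–340 pairs); at these sizes the full suite
and the acceptance run each complete in a few minutes on one CPU. The
chance-level check averages three label permutations because a single
permutation's mean fold AUROC still carries sampling noise of ±0.05–0.1 at
a few hundred samples.

## Known limitations

- FSIM's reference constants were tuned for natural 8-bit images; the
  rescaling to L = 1 preserves the algebra but not necessarily the
  perceptual calibration on sparse renders.
- The renderer's first-hit convention ignores translucency; internal eye
  structures visible through thin tissue in real renders are not modeled.
- Brain masks are inputs (or synthetic); no brain-extraction algorithm is
  bundled, so mask-quality pathologies beyond the BHR indicator are out of
  scope.
- The greedy fold builder optimizes class balance, not scan-count balance
  per class; with very few, very unequal subjects the per-fold class share
  can deviate by several points from global.
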