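# Methods

This note documents the models, parameters and design choices behind the
package: a class-interpolating GAN augmentation method ("DreamOn") and the
noise-robustness benchmark built around it.

## Problem setting

Three-class classification of grayscale medical-style images (normal /
benign / malignant breast-ultrasound appearance) under distribution shift.
The emulated reference collection has 780 images at class proportions
17% / 56% / 27% — apportioned to (133, 437, 210) — each with a binary
lesion segmentation mask (blank for normal), split 600 / 90 / 90 into
train / test / validation.  Robustness is probed by corrupting the test
set with parametric noise at geometrically increasing intensities and
tracking how balanced accuracy and calibration degrade.

## Synthetic phantoms

Real ultrasound imagery cannot be redistributed with the package, so a
phantom generator supplies datasets with the same statistical structure:

* background — multiplicative speckle texture: a mid-gray base modulated
  by low-pass-filtered Gaussian noise (`speckle_contrast`, default 0.35);
* benign — one smooth darkened ellipse (random axes, orientation and
  position); its mask is the ellipse;
* malignant — one jagged dark region (a 14-vertex radial polygon with
  ±40% radius perturbation) plus a darker "acoustic shadow" column
  beneath; its mask is the polygon;
* normal — texture only, blank mask.

Class counts use largest-remainder apportionment with ties broken toward
the lower class index, which reproduces (133, 437, 210) at n = 780.
Splitting is stratified on the dominant class (two-stage
`train_test_split`), keeping per-split proportions within rounding of the
whole.  Every image is a pure function of `(seed, index)`.

The phantoms are deliberately simple: separable at small image sizes by a
shallow network, with no beamforming, attenuation or probe geometry.
Passing tests therefore demonstrate that the pipeline's mechanics
(composition rules, conservation laws, metric definitions, checkpointing,
determinism) are correct — not that any accuracy number transfers to real
ultrasound data.

## Noise ladders

Three families model common ultrasound distortions, each applied at six
perturbed levels plus the clean level 0, with `intensity(k) = base ·
2^(k−1)`:

| family | model | base (default) |
|---|---|---|
| gaussian | `x + N(0, σ²)`, clipped to [0, 1] | σ₀ = 0.02 |
| speckle | `x + x·N(0, σ²)`, clipped | σ₀ = 0.05 |
| salt & pepper | each pixel corrupted w.p. d, set to 0 or 1 (50/50) | d₀ = 0.005 |

The reference description fixes only the doubling rule and that the top
level drives models to chance (~33% for three classes); the defaults above
make level 6 severely degraded on [0, 1] imagery (gaussian σ = 0.64,
speckle σ = 1.6, corruption density 0.16).  The principled route is
`calibrate_base_intensity`, which bisects the base intensity (≤ 20
iterations, 1e-3 tolerance) until a single reference model's balanced
accuracy at level 6 falls inside a chance band; whether the original
calibration used one model or a pool is unknown, so one model is the
interface.  Speckle is modeled as multiplicative Gaussian and the
salt/pepper polarity split 50/50 — both standard conventions the source
description leaves open.

## Comparison augmentations

* **SDA** — rotation uniform in ±15° (bilinear, zero padding), horizontal
  flip with p = 0.5, then multiplicative brightness and contrast jitter
  (default ±20%, unspecified in the reference and therefore configurable),
  clipped.  Vertical flips are never applied — they invert the
  shadow-below-lesion geometry.
* **Pixel-space Mixup** — `λ·x + (1−λ)·y` on images and labels with
  `λ ~ Beta(α, α)`, α = 0.8; partners drawn uniformly across classes.  One
  mixed set is materialized per training run (the "dataset" framing of the
  composition table) rather than resampled each epoch.
* **Manifold mixing** — the same convex rule applied to hidden
  representations during training with the model's current weights.  The
  eligible mixing points are the raw input and the output of each network
  stage, drawn uniformly per batch.  Both batches run through the shared
  head in one stacked forward pass so layer caches stay consistent; the
  gradient splits λ / (1−λ) across the two branches.

Every non-vanilla training set is the originals plus a same-size augmented
set (600 + 600 = 1,200 at reference scale); `mixed_fraction` (default 0.5
of the final set) controls how much of the augmented half is mixed.

## The generative pipeline

`G_m` is an unconditional DCGAN-style generator trained only on the
masks; blank masks are legitimate samples so the prior covers the
lesion-free class.  `G_s` is conditional: the mask is encoded by strided
convolutions to a 4×4 grid, the 400-dimensional standard-normal noise
vector and the 3-dimensional class vector are fused by a dense layer into
a parallel 4×4 block, and the concatenation is decoded to the image.  The
discriminator for `G_s` sees (image, mask, class vector) as stacked
channels.  Decoders use nearest-neighbour upsampling followed by 3×3
convolution — the same lineage as transposed convolution but with milder
checkerboard artifacts (which are tolerated, not corrected, and shared by
the DreamOff control).  Both GANs train with the non-saturating BCE
objective and Adam (2e-4, β = 0.5/0.999).

Training uses only one-hot class vectors.  Interpolation happens purely at
synthesis time: a class pair is chosen uniformly among the three unordered
pairs, and the first class's weight is drawn from `Beta(κμ, κ(1−μ))` with
κ = 2 and pair means μ solving the linear system `E[w] = proportions`
(the free parameter closed symmetrically, μ_nb = μ_nm, giving
(0.255, 0.255, 0.935) for proportions (0.17, 0.56, 0.27)).  Draws are
clamped to (1e-3, 1−1e-3) so both weights stay strictly positive.  A
generated set's weight list is resampled (≤ 10 attempts) until each
per-class mean is within tolerance of the proportions; the 0.02 tolerance
is defined at the reference size 600 and widens by √(600/n) for smaller
sets, where a fixed band is unattainable (a single 2-sparse draw always
zeroes one class).  The emitted class vector is the ground-truth label;
one-hot vectors tag the sample `dreamoff`, interpolated ones `dreamon`.
Masks are drawn unconditionally for both; whether the original mask prior
was itself interpolated per class mixture is ambiguous in the source and
deliberately not guessed.

## Classifier and training protocol

The classifier is a residual CNN in the package's own CPU layer framework
(explicit forward/backward per layer, im2col convolution, batch
normalization, Adam), validated end-to-end by finite-difference gradient
checks.  `arch_scale='full'` is an 18-layer network (stem + 4 stages × 2
basic blocks, widths 64–512); `'tiny'` (stem + 2 single-block stages,
widths 16/32) is the desk-scale variant every test and the acceptance
script use.  Defaults follow the reference protocol: 100 epochs, batch
size 20, Adam 1e-3 with β = 0.9/0.999, random initialization, no schedule,
no early stopping, five runs per strategy.  The loss is soft-target
cross-entropy `−Σ w_c log p_c`, which reduces to ordinary cross-entropy
for one-hot labels.  After every epoch the balanced accuracy on the
validation split (argmax vs. dominant class; validation imagery is
original, so labels are one-hot) is recorded and the best checkpoint kept,
earliest epoch on ties.  Inputs are per-image min-max scaled and centered
to [−1, 1] (input resolution and normalization are unspecified in the
source; both are configurable).

## Metrics

* **Balanced accuracy** — mean per-class recall over the classes present
  in the truth (delegated to scikit-learn).
* **ECE** — confidence = max probability; 10 equal-width right-closed
  bins, empty bins skipped (the bin scheme is unspecified in the source;
  this is the dominant convention).
* **Δ stability** — max − min of the per-level median balanced accuracies
  for one strategy/family; medians over five runs are the exact middle
  order statistic.
* **Above-chance threshold** — the (1−α) quantile of Binomial(n, 1/3)
  divided by n.  For n = 90 and α = 0.05 this is 37/90 ≈ 0.411, matching
  the printed reference value; note the exact Clopper–Pearson upper bound
  for 30/90 would be ≈ 0.42, so the quantile convention is the one that
  reproduces the printed number.  The discrepancy is documented, not
  resolved.
* **Fleiss' kappa** — statsmodels' fixed-panel implementation behind a
  validating wrapper; the fully degenerate single-category table (expected
  agreement 1) is defined as κ = 1.  Landis–Koch bands are attached as
  text only.

## Problem sizes

Tests and the acceptance script run the tiny configuration: 130 phantoms
at 32 px (split 100/15/15), GANs at width 8 for 200 steps with batch 16,
the tiny classifier for 8 epochs, one run, and the gaussian ladder for the
end-to-end smoke.  These sizes are the package's chosen desk-scale
defaults; the full-scale protocol (128 px, 18-layer network, 100 epochs,
five runs, all three families) is exposed through the same interfaces and
the YAML config.

## Known limitations

* Phantom separability means absolute accuracies are near-ceiling at level
  0 and the benchmark's interesting signal is the *degradation profile*,
  not the clean numbers.
* GAN image quality at 200 steps/32 px is crude; no FID/IS scoring is
  attempted, and DreamOn's accuracy advantage over DreamOff on real data
  is not reproduced here — only the machinery that would measure it.
* The human-observer side is protocol construction and agreement
  statistics only; no psychophysical data ships with the package.
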