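# Methods

This document records the models, procedures, parameter choices and numerical
conventions implemented by `cardioda`.

## Problem setting

Two imaging domains share the same anatomy but differ in appearance:

- **source**: CT-like contrast — bright blood pools, high contrast-to-noise;
  always fully labelled.
- **target**: MR-like (b-SSFP-like) contrast — compressed and re-ordered
  tissue intensities, stronger noise, a smooth multiplicative-style bias
  field; labelled only for a fraction `p` of cases.

The task is 7-class segmentation (background + LV, MYO, RV, LA, RA, AA) of
target volumes. Supervision levels are `p ∈ {0, 0.1, 0.2, 0.3}`; the number
of labelled target cases is `floor(p · n_target)` (so 2/4/6 of 20 and
5/10/15 of 51).

## Synthetic phantom

`cardioda.phantom` generates cohorts from three independent ingredients:

1. **Anatomy** — six structures in normalised coordinates: an LV ellipsoid
   enclosed by a MYO ellipsoidal shell, RV/LA/RA ellipsoids, and an AA tube
   along z. A smooth random displacement field (Gaussian-filtered white noise,
   σ = 4 voxels, default amplitude 1.5 voxels) individualises each case. The
   anatomy is controlled by `anatomy_seed` alone.
2. **Appearance** — per-domain piecewise-constant intensity plateaus per
   label, plus a low-frequency cosine bias field and additive Gaussian noise.
   The target plateaus are deliberately compressed and re-ordered relative to
   the source so that a source-trained classifier fails on raw target images.
3. **Noise seed** — derived by hashing `(seed, domain)` so that paired
   source/target cases share anatomy but not noise.

What the phantom emulates: a controllable cross-modality appearance gap over
identical multi-structure anatomy, anisotropic voxels (1×1×2 mm default),
bias-field inhomogeneity. What it does not emulate: realistic cardiac shape
variability, partial-volume effects, motion or flow artefacts, real MR/CT
physics. Conclusions from it are about the adaptation machinery, not about
clinical accuracy.

## Preprocessing (`cardioda.imaging_io`)

- Heart-centred crop: a square in-plane box around the foreground centroid,
  clamped to the volume; the box is half-open `[lo, hi)`, 0-based.
  `margin=None` sets the crop extent equal to the output size (resize factor
  exactly 1, enabling a voxel-exact round trip).
- Per-branch normalisation: the GAN branch scales each slice to `[-1, 1]`
  (a constant slice maps to zeros); the VAE and UNet branches standardise
  each volume to zero mean, unit variance (a constant volume is rejected).
- Axial slicing with recorded `CropGeometry`; `reassemble` resizes predicted
  label slices back with nearest-neighbour interpolation and pastes them into
  a zero background, so the inverse is exact when the resize factor is 1.

## GAN branch (adversarial translation + segmentation)

Components: a source→target generator, a shared encoder, a decoder acting as
the reverse generator, a pixel classifier on encoder features, patch
discriminators for the image and translated-image distributions, and an
optional feature discriminator (enabled by default, weight 0.1).

Losses (least-squares GAN form `(D(x) − label)²`):

- adversarial terms for translation and back-translation,
- L1 cycle-consistency (weight 10),
- segmentation loss = soft Dice + pixel cross-entropy on translated source
  images with source labels (weight 1),
- **semi-supervised addition**: the same segmentation loss on the subset of
  target slices whose case is in the supervision plan (weight 1). With an
  all-false supervised mask this term is exactly 0 and the total reduces to
  the unsupervised objective.

Training alternates a generator/classifier update with a discriminator
update (Adam, lr 2e-3, β = (0.5, 0.999)).

## VAE branch (dual variational encoders with latent alignment)

- One encoder per domain produces `μ` and `σ = exp(logσ)`; sampling uses the
  reparameterization `z = μ + σ ⊙ ε`.
- KL to the standard normal prior in closed form
  `½ Σ (μ² + σ² − 1 − ln σ²)`, averaged per element.
- **Latent discrepancy**: squared distance between the batch-mean `μ` maps of
  the two domains (default); an MMD variant with a Gaussian kernel is
  available via `kind="mmd"`. This is the explicit domain-alignment term.
- Label-conditioned reconstruction: the decoder receives `z` concatenated
  with a 7-channel condition at latent resolution — downsampled one-hot
  ground truth where labels exist, the classifier's predicted soft maps
  otherwise. Supervised target slices blend in their ground truth via the
  supervision mask.
- A shared classifier segments both domains; source segmentation is always
  supervised, target segmentation only on masked slices (zero when the mask
  is all false).

Default weights: reconstruction 1 per domain, KL 0.01, discrepancy 0.1,
segmentation 1 per domain. One Adam optimiser over all components.

## UNet baseline

A standard 2D encoder–decoder with skip connections (strided-convolution
downsampling, nearest-neighbour upsampling), trained only on labelled target
slices with an augmentation policy: random affine (rotation ±15°, scale
0.9–1.1), mirror (p = 0.5), Gaussian noise (sd up to 0.1 of the intensity
range), Gaussian blur (σ 0.5–1), intensity scaling 0.9–1.1. It has no
unsupervised mode; `p = 0` is rejected.

## Protocol

- Patient-wise k-fold cross-validation on target cases: shuffled ids split
  into k validation folds; every case is validated exactly once.
- Supervised cases are drawn uniformly from each fold's training cases, never
  from its validation cases.
- Batches are unpaired: source and target slices are drawn independently
  (uniform over cases, then uniform over slices); the supervised mask marks
  target slices whose case is in the supervision plan.
- The experiment grid is methods × supervision levels with the UNet skipping
  `p = 0` (11 cells at the default four levels).

## Evaluation conventions

- 3D Dice per label: both masks empty → 1.0; exactly one empty → 0.0.
- ASD: border voxels under 6-connectivity, exact physical nearest-neighbour
  distances (KD-tree) under the anisotropic spacing, symmetric pooled
  average. An empty mask makes ASD undefined → NaN with a warning.
- Volumes in mL = voxel count × voxel volume (mm³) / 1000.
- Volume agreement over cases: signed differences `gt − pred`, reported as
  mean ± sample std (ddof 1) and RMSE; RMSE ≥ |mean| always.
- Paired Wilcoxon signed-rank (two-sided, exact for n ≤ 25, zero differences
  dropped); fewer than two non-zero differences → missing result. Tiers:
  `p ≤ 1e-3`, `p ≤ 5e-2`, else not significant.

## Numerical and design choices

- **No deep-learning framework**: the environment provides none, so
  `cardioda.nn` implements a tape-based reverse-mode autodiff over float32
  numpy arrays (im2col convolution, nearest upsampling, fused
  softmax-cross-entropy, Adam). All gradients are validated against numerical
  differentiation in `tests/test_nn.py`.
- **Desk-scale problem sizes**: the package's own reference experiment is a
  20 + 20 cohort at 64×64×16 voxels, 32×32 network inputs, width 8, 2 folds,
  200 steps per fold. These sizes are chosen so the full semi-supervision
  boost experiment runs in minutes on one CPU while preserving the
  qualitative effect (Dice at `p = 0.3` far above `p = 0` for both branches).
- **Per-slice supervision masking**: target supervision is applied per slice
  via the batch mask; a per-case formulation is the special case where all
  slices of a case share the mask value, so the slice-level mechanism
  subsumes it.
- **Single-level latent code** in the VAE branch (one latent resolution)
  keeps the alignment term interpretable; the discrepancy default is the
  squared distance between batch-mean `μ` maps because it is deterministic,
  cheap and differentiable, with MMD available for heavier-tailed matching.
- **Determinism**: every stochastic component (phantom, fold shuffling,
  supervision selection, batch sampling, weight init, reparameterization
  noise, augmentation) is driven by an explicit seed; training twice with the
  same seed yields bit-identical parameters and metrics.
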