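# Methods

## Problem

Distinguish neuromyelitis optica spectrum disorder (NMOSD) from multiple
sclerosis (MS) from 3D brain imaging of white-matter lesions.  Both diseases
produce scattered T2-FLAIR hyperintensities with overlapping spatial
distributions, cohorts are small (tens of subjects), and 3D convolutional
classifiers are over-parameterised for such data.  The package implements a
two-view *compression block* that folds a 3D volume into 2D multi-channel
maps so that compact 2D residual networks — including ImageNet-pretrained
backbones — can classify whole volumes, together with 3D residual baselines,
the preprocessing pipeline, a synthetic phantom generator and a repeated
cross-validation harness.

## Model

### Compression block

For a cube volume `x(h, w, l)` one spatial axis is folded into the channel
axis:

    x(h, w, l)  →  x1(c=h, w, l)      (view 1)
    x(h, w, l)  →  x2(c=w, h, l)      (view 2)

Each view then passes through a single 2D convolution (kernel 7, stride 3,
32 output channels, no bias), batch normalisation (non-affine) and ReLU:

    y_i = ReLU(BN(conv2d(x_i)))           i = 1, 2
    y   = concat(y1, y2)                  (64 channels)

The spatial output extent per axis is `floor((S − 7)/3) + 1`, i.e. 32 for
S = 100.  Folding along two different axes and concatenating retains
cross-axis structure a single folded view would lose.

### Classifier families

- `two_view_2d` — the fused 64-channel map enters a standard 18- or
  34-layer 2D residual backbone **at its first pooling stage**: the 7×7 stem
  convolution and its normalisation are omitted, since the fused map already
  has the 64 channels the first residual stage expects.  Head: global
  average pooling → dropout (0.15) → 2-unit affine layer.  Because stage
  names and shapes match a standard 2D residual network exactly, pretrained
  backbone weights load without any adapter (`load_pretrained_backbone`);
  compression branches and the output layer stay freshly initialised.
- `resnet3d` — a standard 18/34-layer 3D residual baseline: single-channel
  7×7×7 stem with bias, 3×3×3 block convolutions without bias, 1×1×1
  downsample projections with bias, affine normalisation throughout.

These reference configurations reproduce the published complexity totals
exactly (11,475,330 / 21,583,490 parameters for the two-view models,
33,161,986 / 63,471,618 for the 3D baselines), which is the main structural
check in `tests/test_acceptance.py` and `scripts/acceptance.py`.

The compression convolution takes 98 input channels while volumes are
100³: the folded axes are centre-cropped by one voxel per side immediately
before folding.  This is the minimal interpretation of the stated
ingredients consistent with the printed parameter totals; the non-folded
axes keep their full extent.

### Numerical engine

No deep-learning framework is used: `lesionview.nn` is a compact numpy
layer engine (im2col convolutions backed by BLAS matmuls, batch
normalisation, max/global pooling, dropout, a linear layer, softmax
cross-entropy, SGD with momentum 0.9) with explicit forward/backward passes.
Every layer's gradient is verified against central finite differences in
`tests/test_nn.py`, and the convolution against a brute-force direct
cross-correlation oracle.  All computation is float32.

Initialisation is He-uniform for convolutions and the linear layer, zeros
for biases, deterministic under a supplied seed.  The final normalisation
gain of every residual block is initialised to zero so each block starts as
the identity; without this, training at learning rate 0.01 with batch size 4
diverges intermittently on small cohorts.  Normalisation running statistics
are buffers, never counted as learnable parameters.

## Preprocessing

1. **Crop kernel** — tightest bounding box of voxels strictly above a
   background threshold (default 0; skull-stripped exports pad with exact
   zeros), computed on the FLAIR volume only and reused on the lesion mask.
   The kernel is per-subject; a single cohort-wide box would couple subjects
   through a shared statistic.
2. **Cube resize** — each (w, l) section is resized in-plane first, then the
   stack is resampled along h, to 100³ by default.  Masks use
   nearest-neighbour (and therefore stay binary), intensities bilinear.
   The two-pass route differs from one trilinear pass only in interpolation
   order; constants are preserved exactly either way.
3. **Intensity normalisation** — per-volume min–max to [0, 1]; constant
   volumes map to 0.
4. **Augmentation** — random integer shifts in [−2, 2] voxels per axis
   (zero-filling vacated voxels) and a coin-flip left–right flip (w axis),
   4 copies per subject by default; image and mask receive identical
   transforms; applied to training folds only.  Magnitudes are conventional
   choices for rigid-ish brain volumes; transforms can only move or remove
   lesion voxels, never create them.

## Synthetic phantoms

Each phantom is an ellipsoidal brain (≈32% of the cube) with an elongated
central ventricle proxy.  Lesions: random spheres are seeded either in a
periventricular shell (within 10% of the cube side of the ventricle) with
probability `periventricular_affinity`, or uniformly in white matter; the
sphere union is Gaussian-smoothed and thresholded at exactly the drawn
lesion-voxel target, giving irregular, confluent shapes and an *exact*
lesion fraction (mask voxels / brain voxels).  FLAIR intensity = tissue base
0.55 with smooth texture, ventricle 0.18, lesions 0.95, plus Gaussian noise
(sd 0.05), clipped so brain voxels stay positive and background stays
exactly zero.

The lesion-volume fraction is drawn per subject from a **gamma distribution
moment-matched** to the configured class mean and sd (defaults: MS
0.66% ± 0.65%, NMOSD 0.26% ± 0.37% of brain volume, mirroring the study
cohort's normalized lesion burdens).  A zero-truncated normal was
considered and rejected: both classes have sd > mean (coefficient of
variation up to ≈1.4), which no truncated normal can realise — truncation
would also inflate the realised mean ≈25% above the configured value.  The
gamma matches both moments exactly and is strictly positive.

Default spatial affinities (MS 0.5, NMOSD 0.7) overlap deliberately: with
the default burdens the two classes are hard to separate, as in the clinic.
`PhantomParams.easy()` is the separability dial — a 10× burden gap
(2% vs 0.2%, small sds) and opposite affinities (0 vs 1) — used to verify
that the classifier learns when a strong signal exists.

What the phantoms do **not** emulate: real anatomy (gyri, tissue classes),
scanner physics (bias fields, partial volume, acquisition variation),
registration error, or segmentation noise.  Passing tests therefore
demonstrate that the architecture, optimisation and evaluation machinery
work and that the pipeline can extract burden/location signal — not that
the published clinical accuracies transfer to real cohorts.

## Evaluation protocol

- Five-fold cross-validation with *random* (not stratified) near-equal
  groups, independently reshuffled in each of 15 repeats (both counts
  configurable); every subject is validated exactly once per repeat.
- Fresh model per (repeat, fold), seeded from the master seed and the
  indices; pretrained backbone weights reloaded each time when configured.
- SGD, initial learning rate 0.01 decayed by 10% every ten epochs
  (`lr(e) = 0.01·0.9^⌊e/10⌋` — "every ten steps" is read as epochs, since
  per-iteration decay would collapse the rate within one epoch at this data
  size), momentum 0.9, batch size 4, two-class cross-entropy.  Total epochs
  are a required config value.
- Default network input is the binary lesion mask; the raw FLAIR or the
  mask-restricted FLAIR are selectable (`input_mode`), since which of the
  three the study fed its network is not pinned down.
- Per-repeat metrics pool the five folds' confusion counts (fold-level
  metric averaging is available via ``pool_folds=False``); aggregates are
  mean ± sd (ddof 0) across repeats.  Positive class defaults to NMOSD (the
  rarer disease being detected) and is recorded in every report.
- Reports carry full provenance (per-fold train/validation ids, seeds,
  confusions), from which the test suite asserts the no-leakage and
  metric-algebra invariants on every emitted report.

## Problem sizes used in the test suite

Structural checks (parameter totals, shape laws, transfer, checkpointing)
run at the full 100³ reference geometry.  Behavioural cross-validation runs
use scaled cohorts chosen to keep the suite practical on a single CPU while
leaving the protocol intact: the easy-mode learnability check uses 40+40
phantoms at side 64 (62 per-view channels), depth 18, 20 epochs, 2 repeats
× 5 folds; the shuffled-label null check uses 24 phantoms at side 32 with
5 epochs.  Generator calibration uses 50 draws per class at side 48.  The
cube side scales compute only; the class-separation parameters, protocol
and thresholds are unchanged.

## Known limitations

- No orientation handling: NIfTI axes are taken as stored.  Cohorts mixing
  orientations must be harmonised upstream.
- The numpy engine targets these two architectures; it has no autograd, so
  new topologies require hand-written backward passes.
- Batch normalisation with batch size 4 gives noisy statistics; epoch
  losses are correspondingly spiky (the tests assert late-phase averages).
- 3D baselines train an order of magnitude slower than the two-view models
  (that asymmetry is the architecture's point) — training them at full
  resolution on CPU is possible but slow.
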