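# Methods

## Model

`msgan` synthesizes a contrast-enhanced (T1CE-like) axial MR slice from two
co-registered non-enhanced slices with a conditional GAN in the pix2pix
family. The generator departs from the single-input U-Net in one way that
is the point of the package: each input sequence is encoded by its own
weight-independent four-block encoder, and the decoder fuses the
same-resolution feature maps of *both* encoders at every decoding level by
channel concatenation. Intuition: low-level features keep position and
detail, high-level features keep semantics, and the two sequences carry
complementary tissue contrast; concatenating both pyramids level by level
lets the decoder use whichever source carries the relevant signal at each
scale.

Architectural specifics, with the reasoning where a choice was open:

- **Encoder blocks**: 4×4 convolution, stride 2, padding 1 → instance
  normalization → leaky ReLU (slope 0.2). The 4×4/stride-2 geometry is
  forced by the published halving sequence 256 → 128 → 64 → 32 → 16 with a
  4×4 kernel; the activation slopes follow the pix2pix convention the
  design builds on. Instance (not batch) normalization because generation
  is per-image, not per-batch.
- **Bottleneck**: the two deepest features (2 × 512 @ 16×16) are
  concatenated and mapped by a 3×3 convolution back to 512 channels. The
  published fused widths (1536 = 3·512, 768 = 3·256, 384 = 3·128,
  192 = 3·64) require a *third* same-width tensor at every fusion besides
  the two encoder skips; a learned bottleneck over the joint deepest
  representation is the only arity consistent with all four widths. This
  is a reconstruction, not a uniquely determined reading.
- **Decoder blocks**: 4×4 stride-2 transposed convolution → instance norm
  → dropout (0.5, first two blocks only — the "regularization modules") →
  ReLU. Dropout is disabled at evaluation by default (standard semantics),
  configurable to test-time dropout.
- **Head**: 2× nearest-neighbour upsampling, 3×3 convolution to the output
  channels, Tanh. Outputs therefore live in [−1, 1], which dictates the
  data normalization below.
- **Weight init**: zero-mean Gaussian, sd 0.02, fully seeded; two builds
  from one seed are bit-identical.
- **Single-input mode** keeps one encoder (fused width 2× encoder width)
  and serves as the pix2pix-style baseline configuration; it is a
  degenerate configuration of this model, not a faithful pix2pix port.

The discriminator is the canonical 70×70 patch discriminator: three
stride-2 4×4 convolutions (64/128/256 channels, no norm after the first),
then two stride-1 4×4 convolutions ending in a 1-channel logit map. The
published description fixes "all-convolutional, n×n output, average as the
score" but not the depth; the 70×70 stack is the baseline it inherits.
`receptive_field` exposes the analytic r ← r + (k−1)·j recurrence.

## Objectives

Generator loss `L_G = L_adv + λ·L_pix` with λ = 100 and L1 pixel loss
(less blur than L2). The adversarial value conditions the discriminator on
pairs: D(x1,y), D(x2,y) real terms (summed, as published) and
D(G(x1,x2),y) fake term. The published figure caption instead describes an
unconditional discriminator over real/generated enhanced images only; both
readings are implemented as discriminator modes (`paired`, the literal
default, and `unconditional`), and the mode is recorded in configs and
logs. All training-path probabilities stay in logit space through a safe
softplus; probability-space evaluation exists for reporting and rejects
exactly saturated values. The generator's trained adversarial term is the
literal fake term by default, with a non-saturating `−log D` variant for
small-scale stability; the logged records satisfy
`total = adv + λ·pix` exactly in either mode.

## Data handling

BraTS-style subjects are directories of four NIfTI volumes (T1, T2, FLAIR,
T1CE; nominally 240×240×155) plus integer segmentation labels, discovered
by configurable filename suffixes. Axial slices are selected where the
labelled lesion has at least `min_lesion_pixels` voxels (default 1 — the
exact published selection rule that produced its image counts is not
reconstructible, so the threshold is exposed rather than guessed).
Normalization is per-slice: clip to the 1st–99th percentile window of
nonzero voxels (robust to scanner-scale outliers), then map affinely to
[−1, 1] to match the Tanh head; an absolute window can override the
percentiles when the intensity scale is known. Constant slices map to
zero. 240×240 slices are zero-padded (value −1) onto the 256×256 canvas
rather than resampled, keeping voxel geometry exact. Single-channel slices
are replicated across the three model input channels at batch-assembly
time.

## Phantoms

The phantom generator emulates exactly the statistical structure the model
consumes and nothing more: co-registered sequences sharing one geometry,
sequence-specific contrast, and lesion-specific enhancement. A slice is a
nested-ellipse "brain" of discrete tissue classes plus an elliptical
lesion (rim + concentric core), rendered per sequence through a
class → intensity lookup with additive Gaussian noise (sd 0.03 by default
— a few percent of the dynamic range, typical of normalized MR slices).
The enhanced target is the mean of the two input lookups plus an
enhancement offset (0.35) inside the core. The default lookups make the
rim isointense with surrounding tissue in T1 and the core isointense with
the rim in T2, so **no function of either input alone can reproduce the
target**; this identifiability property (asserted by tests) is what makes
the dual-vs-single comparison meaningful. Lesion geometry jitters
deterministically per slice index; everything is reproducible from
`(seed, index)`. Phantoms can be exported as PNG + manifest or as thin
BraTS-layout NIfTI mini-subjects (uint16, scanner-like arbitrary units),
which is how the loader is round-trip tested.

What phantoms do *not* model: anatomy, MR physics, bias fields, partial
volume, registration error, inter-subject variability. Passing tests
therefore show the pipeline and the architecture's use of joint
information are correct, not that clinical-quality synthesis is achieved.

## Training and evaluation

Per batch: one discriminator step (fake detached) then one generator step,
both Adam (β = 0.5/0.999), base lr 2·10⁻⁴ (unpublished; the pix2pix
convention), cosine-annealed per epoch from lr₀ to 0. Cross-validation is
subject-level: seeded shuffle, round-robin assignment into k folds (sizes
differ by ≤ 1), one model trained per fold and evaluated on its held-out
subjects. Histories log step, epoch, lr, adv, pix, total and d_loss;
checkpoints are self-describing npz archives (weights + config + seed).

Metrics are computed on the [0, 1] rescale of the [−1, 1] model range
(applied identically to reference and candidate), data range 1: NMSE
(residual energy over reference energy), RMSE, PSNR (infinite for
identical pairs — flagged and excluded from means), and SSIM (11×11
Gaussian window, σ 1.5, k₁ 0.01, k₂ 0.03, population local statistics).
The published work does not state its metric formulas or data range, so
absolute reproduction of its table magnitudes is out of scope; the
fold-summary *arithmetic* (Average rows, best-in-row markers) is checked
against the published tables instead, which are shipped as worked-example
inputs in `msgan.reference_results`. Four published Average cells are not
the 3-dp rounding of their published fold values (three consistent with
averaging unrounded data; one 0.04 arithmetic slip); the module documents
them and tests pin them.

The Dunnett many-to-one test uses pooled-variance t statistics; the
two-sided critical value is the 1−α quantile of max|T_i| under the joint
null, estimated by seeded Monte Carlo that draws group means, a shared
control mean and one pooled chi-square scale per replicate — exact for
unequal group sizes, rather than table lookup (default n_mc = 100 000;
doubling n_mc moves the value by < 1 %). Both per-fold and per-image
sampling units are supported and recorded, since the published analysis
does not state which entered the test. α defaults to 0.05, two-sided.

## Desk-scale experiment protocols (`msgan.experiments`)

Full-scale training (120 epochs, batch 64, 256×256, hundreds of subjects)
is a multi-day GPU workload and is not a verification target here. The
frozen desk-scale protocols are:

- **Architecture trace**: one 3×256×256 forward pass recording every named
  stage; this is the exact check of the printed dimension ledger.
- **Overfit smoke**: 8 phantom slices at 64×64, 200 steps, batch 8,
  half-width networks (base 32); the pixel loss must fall below half of
  its first-10-step mean. Verifies the full adversarial loop optimizes.
- **Dual vs single**: 32 phantom slices (24 train / 8 held out) at 64×64,
  150 steps, quarter-width networks (base 16), five paired seeds; the
  dual-encoder model should beat the single-input variant in held-out SSIM
  in ≥ 4 of 5 seeds. Widths are reduced because the property under test —
  exploiting information present only jointly — is width-independent,
  and this keeps ten training runs within minutes on one core.
- **Dunnett calibration**: 2 000 simulated global-null replications
  (5 treatments + control, n = 20) must reject at 0.05 ± 0.02.

## Numerical notes and limitations

The network substrate is a reverse-mode autodiff over numpy float32:
convolutions via an offset-major im2col and one GEMM (stride-1 input
gradients are computed as a convolution of the output gradient with the
flipped transposed kernel, avoiding a pathological thin-K GEMM), instance
norm with the standard fused backward, seeded dropout streams that advance
only in training mode. Gradients are verified against central differences
in the test suite. Runs are bit-reproducible on one machine but, as with
any BLAS-dependent code, not guaranteed identical across BLAS builds.
There is no GPU path, no mixed precision, and no multi-scale or
spectral-normalized discriminator; 3-D volumetric generation and more than
two input modalities are out of scope.
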