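# msgan — multi-sequence GAN for contrast-enhanced MRI synthesis

Gadolinium-based contrast agents make T1-weighted contrast-enhanced (T1CE)
brain MRI possible, but they are contraindicated for some patients and
carry real adverse-effect risk. `msgan` implements a conditional
image-to-image GAN that synthesizes T1CE-like axial slices from **two**
co-registered non-enhanced sequences (e.g. T1 + T2), for researchers
studying multi-modal MR-to-MR translation on BraTS-style data.

## The model

The generator is a dual-encoder fusion U-Net. Each input sequence gets its
own four-block encoder (stride-2 4×4 convolutions, instance normalization,
leaky ReLU), so for a 3×256×256 input the feature pyramids are
64×128×128 → 128×64×64 → 256×32×32 → 512×16×16. A bottleneck maps the
concatenated deepest features back to 512 channels, and the decoder fuses
the same-resolution features of *both* encoders at every level by channel
concatenation — fused widths 1536, 768, 384 and 192 (= 3 × the encoder
width at each level) — before a final upsample + convolution + Tanh head
emits a 3×256×256 image in [−1, 1]. The discriminator is a Markovian
patch discriminator (70×70 receptive field): an all-convolutional stack
producing an n×n logit map whose mean sigmoid is the realism score.

Training minimizes, for the generator,

    L_G = L_adv + λ · L_pix ,    λ = 100

where `L_pix = E‖y − G(x1,x2)‖₁` and the adversarial value is

    L_adv = E[log D(x1,y)] + E[log D(x2,y)] + E[log(1 − D(G(x1,x2),y))]

which the discriminator maximizes. Optimization uses Adam
(lr 2·10⁻⁴, β₁ = 0.5) with cosine-annealed learning rate, subject-level
five-fold cross-validation, and NMSE / RMSE / PSNR / SSIM evaluation with
a Dunnett many-to-one test for model comparison.

A synthetic phantom module generates co-registered multi-sequence slices
whose enhanced target is a known function of *both* inputs (rim visible
only in T2, core contrast only in T1), so the whole pipeline — including
the multi-modal-beats-single-modal comparison — is testable without any
external data.

## Worked example

```python
from msgan.generator import GeneratorConfig, build_generator, trace_shapes
from msgan.phantoms import PhantomSpec, generate_dataset
from msgan.discriminator import build_patch_discriminator, DiscriminatorConfig
from msgan.training import TrainConfig, train

gen = build_generator(GeneratorConfig(), seed=0)
for name, c, h, w in trace_shapes(gen, (3, 256, 256)).entries[8:]:
    print(f"{name:16s} {c:5d} x {h:3d} x {w:3d}")
```

prints the decoder half of the dimension ledger:

```
bottleneck         512 x  16 x  16
fusion_level4     1536 x  16 x  16
decoder_block1     256 x  32 x  32
fusion_level3      768 x  32 x  32
decoder_block2     128 x  64 x  64
fusion_level2      384 x  64 x  64
decoder_block3      64 x 128 x 128
fusion_level1      192 x 128 x 128
upsample           192 x 256 x 256
output               3 x 256 x 256
```

i.e. every fusion concatenates the decoder output with both encoders'
same-resolution skips. A short training run on phantoms:

```python
ds = generate_dataset(PhantomSpec(canvas_side=64, seed=0), 8)
gen = build_generator(GeneratorConfig(base_channels=32), seed=0)
disc = build_patch_discriminator(DiscriminatorConfig(base_channels=32), seed=0)
cfg = TrainConfig(epochs=200, batch_size=8, seed=0, image_side=64)
hist = train(gen, disc, ds.samples, cfg, max_steps=200)
print(f"pixel loss: {hist.records[0]['pix']:.3f} -> {hist.records[-1]['pix']:.3f}")
```

```
pixel loss: 0.429 -> 0.057
```

— the L1 term falls to ~13 % of its initial plateau in 200 steps,
confirming the optimization loop works end to end.

There is also a thin CLI: `msgan trace-shapes --side 256`,
`msgan phantoms --n 64 --out dir/`, `msgan train --config cfg.yaml`,
`msgan cv --config cfg.yaml --k 5`, and `msgan evaluate --reports ...
--control pix2pix-t2`.

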