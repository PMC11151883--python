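"""Dual-encoder fusion generator for cross-sequence MR synthesis.

Two weight-independent convolutional encoders (one per input sequence)
each produce a pyramid of feature maps; a single decoder fuses the
same-resolution features from *both* encoders at every decoding level by
channel concatenation.  With the default four levels and 64 base channels
the fused decoder widths for a 3x256x256 input are 1536, 768, 384 and 192
channels: at every level the fused width is three times the encoder width
(decoder output + two skips).  The head upsamples once more and maps to the
output channels through a Tanh, so images live in [-1, 1].

A ``single_input_mode`` degenerate configuration keeps one encoder only
(fused width = 2x encoder width), serving as the single-sequence baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import nn
from .nn import functional as F
from .checkpoint import load_checkpoint, save_checkpoint


@dataclass
class GeneratorConfig:
    in_channels: int = 3
    out_channels: int = 3
    base_channels: int = 64
    n_levels: int = 4
    kernel: int = 4
    norm: str = "instance"
    encoder_activation_slope: float = 0.2
    dropout_rate: float = 0.5
    n_dropout_blocks: int = 2
    single_input_mode: bool = False

    @property
    def level_widths(self) -> list[int]:
        """Encoder channel widths from shallowest to deepest level."""
        return [self.base_channels * 2 ** i for i in range(self.n_levels)]

    @property
    def n_encoders(self) -> int:
        return 1 if self.single_input_mode else 2


@dataclass
class ShapeTrace:
    """Ordered ledger of named intermediate tensor dimensions."""

    entries: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, stage: str, t) -> None:
        _, c, h, w = t.data.shape
        self.entries.append((stage, int(c), int(h), int(w)))

    def stage_names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def channels(self, prefix: str) -> list[int]:
        return [c for name, c, _, _ in self.entries if name.startswith(prefix)]

    def as_dict(self) -> dict[str, tuple[int, int, int]]:
        return {name: (c, h, w) for name, c, h, w in self.entries}

    def __getitem__(self, stage: str) -> tuple[int, int, int]:
        return self.as_dict()[stage]


class EncoderBlock(nn.Module):
    """Stride-2 4x4 convolution -> instance norm -> leaky activation."""

    def __init__(self, c_in, c_out, kernel, slope, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, kernel, stride=2, padding=kernel // 2 - 1, rng=rng)
        self.norm = nn.InstanceNorm2d(c_out)
        self.act = nn.LeakyReLU(slope)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class Encoder(nn.Module):
    """Four-block (by default) feature-extraction pyramid for one sequence."""

    def __init__(self, config: GeneratorConfig, rng):
        super().__init__()
        widths = config.level_widths
        c_prev = config.in_channels
        self.blocks = []
        for i, c in enumerate(widths):
            block = EncoderBlock(c_prev, c, config.kernel,
                                 config.encoder_activation_slope, rng)
            setattr(self, f"block{i + 1}", block)
            self.blocks.append(block)
            c_prev = c
        self.n_levels = config.n_levels

    def forward(self, x):
        _, _, h, w = x.data.shape
        div = 2 ** self.n_levels
        if h % div or w % div:
            raise ValueError(
                f"shape not divisible: spatial size {h}x{w} must be divisible by {div}")
        feats = []
        for block in self.blocks:
            x = block(x)
            feats.append(x)
        return feats


class DecoderBlock(nn.Module):
    """Transposed 4x4 stride-2 convolution -> instance norm [-> dropout] -> ReLU."""

    def __init__(self, c_in, c_out, kernel, dropout_rate, dropout_seed, rng):
        super().__init__()
        self.deconv = nn.ConvTranspose2d(c_in, c_out, kernel, stride=2,
                                         padding=kernel // 2 - 1, rng=rng)
        self.norm = nn.InstanceNorm2d(c_out)
        self.drop = nn.Dropout(dropout_rate, dropout_seed) if dropout_rate > 0 else None
        self.act = nn.ReLU()

    def forward(self, x):
        x = self.norm(self.deconv(x))
        if self.drop is not None:
            x = self.drop(x)
        return self.act(x)


class Generator(nn.Module):
    def __init__(self, config: GeneratorConfig, seed: int = 0):
        super().__init__()
        if config.n_levels < 2:
            raise ValueError("too shallow: n_levels must be >= 2")
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = config.level_widths
        deep = widths[-1]
        n_enc = config.n_encoders

        self.encoder1 = Encoder(config, rng)
        if n_enc == 2:
            self.encoder2 = Encoder(config, rng)

        # Bottleneck: maps the concatenated deepest features back to the
        # deepest encoder width at unchanged resolution, providing the extra
        # same-width tensor entering the deepest fusion.
        self.bottleneck = nn.Sequential(
            nn.Conv2d(n_enc * deep, deep, 3, stride=1, padding=1, rng=rng),
            nn.InstanceNorm2d(deep),
            nn.ReLU(),
        )

        self.decoder_blocks = []
        for i in range(config.n_levels - 1):
            level = config.n_levels - 1 - i           # level of the fused input
            c_in = (n_enc + 1) * widths[level]
            c_out = widths[level - 1]
            rate = config.dropout_rate if i < config.n_dropout_blocks else 0.0
            block = DecoderBlock(c_in, c_out, config.kernel, rate,
                                 dropout_seed=seed * 1000 + i, rng=rng)
            setattr(self, f"decoder_block{i + 1}", block)
            self.decoder_blocks.append(block)

        self.head_conv = nn.Conv2d((n_enc + 1) * widths[0], config.out_channels,
                                   3, stride=1, padding=1, rng=rng)
        self.head_act = nn.Tanh()

    # -- forward ----------------------------------------------------------

    def forward(self, x1, x2=None, trace: Optional[ShapeTrace] = None):
        cfg = self.config
        if cfg.single_input_mode:
            enc_feats = [self.encoder1(x1)]
        else:
            if x2 is None:
                raise ValueError("input mismatch: dual-encoder generator needs two inputs")
            if x1.data.shape != x2.data.shape:
                raise ValueError("input mismatch: x1 and x2 must share one shape")
            enc_feats = [self.encoder1(x1), self.encoder2(x2)]

        if trace is not None:
            for e, feats in enumerate(enc_feats):
                for lvl, f in enumerate(feats):
                    trace.record(f"encoder{e + 1}_block{lvl + 1}", f)
        return self.fuse_and_decode(enc_feats, trace=trace)

    def fuse_and_decode(self, enc_feats: list, trace: Optional[ShapeTrace] = None):
        """Merge the encoder pyramids level by level and decode to an image.

        ``enc_feats`` holds one feature pyramid (shallow to deep) per
        encoder; at each decoding level the decoder output is concatenated
        with every encoder's same-resolution map.
        """
        cfg = self.config
        if len(enc_feats) != cfg.n_encoders:
            raise ValueError(f"fusion mismatch: expected {cfg.n_encoders} pyramids")
        shapes = {tuple(f.data.shape) for feats in enc_feats for f in feats[-1:]}
        if len(shapes) != 1:
            raise ValueError(f"fusion mismatch: deepest feature shapes differ {shapes}")

        deepest = [feats[-1] for feats in enc_feats]
        bott = self.bottleneck(F.concat(deepest, axis=1) if len(deepest) > 1 else deepest[0])
        if trace is not None:
            trace.record("bottleneck", bott)

        level = cfg.n_levels - 1
        fused = F.concat([bott] + [feats[level] for feats in enc_feats], axis=1)
        if trace is not None:
            trace.record(f"fusion_level{level + 1}", fused)

        for i, block in enumerate(self.decoder_blocks):
            dec = block(fused)
            if trace is not None:
                trace.record(f"decoder_block{i + 1}", dec)
            level -= 1
            fused = F.concat([dec] + [feats[level] for feats in enc_feats], axis=1)
            if trace is not None:
                trace.record(f"fusion_level{level + 1}", fused)

        up = F.upsample_nearest(fused, 2)
        if trace is not None:
            trace.record("upsample", up)
        out = self.head_act(self.head_conv(up))
        if trace is not None:
            trace.record("output", out)
        return out

    # -- persistence ------------------------------------------------------

    def save(self, path):
        save_checkpoint(self, asdict(self.config), self.seed, path)


def build_generator(config: Optional[GeneratorConfig] = None, seed: int = 0) -> Generator:
    return Generator(config or GeneratorConfig(), seed=seed)


def load_generator(path) -> Generator:
    state, config_dict, seed = load_checkpoint(path)
    gen = Generator(GeneratorConfig(**config_dict), seed=seed)
    gen.load_state_dict(state)
    return gen


def encode(encoder: Encoder, image) -> list:
    """Run one encoder, returning its feature pyramid (shallow to deep)."""
    if not isinstance(image, nn.Tensor):
        image = nn.Tensor(image)
    if image.ndim == 3:
        image = nn.Tensor(image.data[None])
    return encoder(image)


def fuse_and_decode(generator: Generator, f1: list, f2: Optional[list] = None):
    """Decode an output image from pre-computed encoder feature pyramids."""
    pyramids = [f1] if f2 is None else [f1, f2]
    return generator.fuse_and_decode(pyramids)


def trace_shapes(generator: Generator, input_shape: tuple[int, int, int],
                 seed: int = 0) -> ShapeTrace:
    """Forward a random input and record every named stage's dimensions."""
    rng = np.random.default_rng(seed)
    c, h, w = input_shape
    x1 = nn.Tensor(rng.uniform(-1, 1, size=(1, c, h, w)))
    x2 = None
    if not generator.config.single_input_mode:
        x2 = nn.Tensor(rng.uniform(-1, 1, size=(1, c, h, w)))
    trace = ShapeTrace()
    was_training = generator.training
    generator.eval()
    generator.forward(x1, x2, trace=trace)
    generator.train(was_training)
    names = trace.stage_names()
    assert len(names) == len(set(names)), "trace stage names must be unique"
    return trace
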