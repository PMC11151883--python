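"""Markovian patch discriminator.

An all-convolutional stack that scores overlapping patches of its input:
the output is an n x n logit map, one logit per receptive field, and the
realism score is the mean of the elementwise sigmoid of that map.  The
default depth (three stride-2 layers followed by two stride-1 layers, all
4x4 kernels) gives the canonical 70x70-pixel receptive field.

In ``paired`` mode the discriminator sees a channel-concatenated
(candidate, target) pair, conditioning realism on the real enhanced image;
in ``unconditional`` mode it sees a single image.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from . import nn
from .checkpoint import load_checkpoint, save_checkpoint


@dataclass
class DiscriminatorConfig:
    in_channels: int = 6          # 3 + 3 for the paired (conditional) mode
    base_channels: int = 64
    n_stride2_layers: int = 3
    kernel: int = 4
    mode: str = "paired"          # "paired" | "unconditional"

    def __post_init__(self):
        if self.n_stride2_layers < 1:
            raise ValueError("n_stride2_layers must be >= 1")
        if self.kernel < 2:
            raise ValueError("kernel must be >= 2")
        if self.mode not in ("paired", "unconditional"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def layer_geometry(self) -> list[tuple[int, int]]:
        """(kernel, stride) per layer: stride-2 stack then two stride-1 layers."""
        return [(self.kernel, 2)] * self.n_stride2_layers + [(self.kernel, 1)] * 2


@dataclass
class PatchMap:
    """Per-patch realism logits and their aggregate probability score."""

    logits: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits))

    @property
    def score(self) -> float:
        return discriminator_score(self)


class PatchDiscriminator(nn.Module):
    def __init__(self, config: DiscriminatorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = config.kernel
        pad = k // 2 - 1
        layers: list[nn.Module] = []
        c_prev = config.in_channels
        # stride-2 pyramid; no norm after the first convolution
        for i in range(config.n_stride2_layers):
            c = config.base_channels * 2 ** i
            layers.append(nn.Conv2d(c_prev, c, k, stride=2, padding=pad, rng=rng))
            if i > 0:
                layers.append(nn.InstanceNorm2d(c))
            layers.append(nn.LeakyReLU(0.2))
            c_prev = c
        # two stride-1 layers, the last emitting the 1-channel logit map
        c = config.base_channels * 2 ** config.n_stride2_layers
        layers.append(nn.Conv2d(c_prev, c, k, stride=1, padding=pad, rng=rng))
        layers.append(nn.InstanceNorm2d(c))
        layers.append(nn.LeakyReLU(0.2))
        layers.append(nn.Conv2d(c, 1, k, stride=1, padding=pad, rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)

    def save(self, path):
        save_checkpoint(self, asdict(self.config), self.seed, path)


def build_patch_discriminator(config: Optional[DiscriminatorConfig] = None,
                              seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(config or DiscriminatorConfig(), seed=seed)


def load_discriminator(path) -> PatchDiscriminator:
    state, config_dict, seed = load_checkpoint(path)
    disc = PatchDiscriminator(DiscriminatorConfig(**config_dict), seed=seed)
    disc.load_state_dict(state)
    return disc


def _to_batch(image) -> np.ndarray:
    arr = image.data if isinstance(image, nn.Tensor) else np.asarray(image)
    if arr.ndim == 3:
        arr = arr[None]
    return arr


def patch_logits(disc: PatchDiscriminator, a, b=None) -> PatchMap:
    """Score an image (unconditional) or an image pair (paired mode)."""
    mode = disc.config.mode
    a = _to_batch(a)
    if mode == "paired":
        if b is None:
            raise ValueError("mode mismatch: paired discriminator needs two images")
        b = _to_batch(b)
        x = np.concatenate([a, b], axis=1)
    else:
        if b is not None:
            raise ValueError("mode mismatch: unconditional discriminator takes one image")
        x = a
    if x.shape[1] != disc.config.in_channels:
        raise ValueError(
            f"mode mismatch: expected {disc.config.in_channels} channels, got {x.shape[1]}")
    out = disc(nn.Tensor(x))
    logits = out.data[:, 0]
    if logits.shape[0] == 1:
        logits = logits[0]
    return PatchMap(logits=logits)


def discriminator_score(patch_map: PatchMap) -> float:
    """Mean sigmoid over the patch logit map — the aggregate realism score."""
    if patch_map.logits.size == 0:
        raise ValueError("empty patch map")
    return float(patch_map.probabilities.mean())


def receptive_field(config: Optional[DiscriminatorConfig] = None,
                    geometry: Optional[list[tuple[int, int]]] = None) -> int:
    """Analytic receptive-field side of one output unit (r <- r + (k-1)*j).

    Pass either a discriminator config or an explicit (kernel, stride)
    layer list.
    """
    if geometry is None:
        geometry = (config or DiscriminatorConfig()).layer_geometry()
    r, j = 1, 1
    for k, s in geometry:
        r += (k - 1) * j
        j *= s
    return r
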