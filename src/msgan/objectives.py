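"""Adversarial and pixel objectives for the conditional translation GAN.

The adversarial value is

    E[log D(x1, y)] + E[log D(x2, y)] + E[log(1 - D(G(x1, x2), y))]

with expectations realized as means over batch and patch entries and
natural logarithms throughout; the second real term is dropped in the
single-input configuration.  The discriminator maximizes this value (we
return its negation so a minimizer can be used), and the generator
minimizes the fake term plus an L1 pixel penalty weighted by lambda.
All training-path computations stay in logit space through a numerically
safe softplus; probability-space evaluation is offered for reporting and
cross-checking and rejects exactly saturated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .nn import functional as F


@dataclass
class LossWeights:
    lambda_pix: float = 100.0

    def __post_init__(self):
        if self.lambda_pix < 0:
            raise ValueError("lambda_pix must be >= 0")


@dataclass
class LossBundle:
    """Generator loss components; total = adv + lambda_pix * pix by construction."""

    adv: float
    pix: float
    lambda_pix: float

    @property
    def total(self) -> float:
        return self.adv + self.lambda_pix * self.pix


def _as_array(m) -> np.ndarray:
    if hasattr(m, "logits"):  # PatchMap
        return np.asarray(m.logits, dtype=np.float64)
    return np.asarray(m, dtype=np.float64)


def _log_d(m: np.ndarray, from_logits: bool) -> float:
    """mean log D over a map, safely."""
    if from_logits:
        return float(-np.logaddexp(0.0, -m).mean())
    if np.any(m <= 0.0) or np.any(m >= 1.0):
        raise ValueError("saturated probability: use logit-space maps")
    return float(np.log(m).mean())


def _log_one_minus_d(m: np.ndarray, from_logits: bool) -> float:
    if from_logits:
        return float(-np.logaddexp(0.0, m).mean())
    if np.any(m <= 0.0) or np.any(m >= 1.0):
        raise ValueError("saturated probability: use logit-space maps")
    return float(np.log1p(-m).mean())


def adversarial_loss(d_real_x1, d_real_x2, d_fake, *, from_logits: bool = False) -> float:
    """Full adversarial value; pass ``d_real_x2=None`` for single-input models."""
    value = _log_d(_as_array(d_real_x1), from_logits)
    if d_real_x2 is not None:
        value += _log_d(_as_array(d_real_x2), from_logits)
    value += _log_one_minus_d(_as_array(d_fake), from_logits)
    return value


def discriminator_loss(d_real_x1, d_real_x2, d_fake, *, from_logits: bool = False) -> float:
    """Negated adversarial value, so minimizing it maximizes the adversarial value."""
    return -adversarial_loss(d_real_x1, d_real_x2, d_fake, from_logits=from_logits)


def pixel_loss(y, y_hat) -> float:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.abs(y - y_hat).mean())


def generator_loss(adv: float, pix: float, weights: LossWeights) -> LossBundle:
    if not (np.isfinite(adv) and np.isfinite(pix)):
        raise ValueError("non-finite loss components")
    return LossBundle(adv=float(adv), pix=float(pix), lambda_pix=weights.lambda_pix)


# -- differentiable (tensor) counterparts used by the trainer -------------


def discriminator_loss_t(real_logit_maps: list[Tensor], fake_logits: Tensor) -> Tensor:
    """-sum_i E[log D(real_i)] - E[log(1-D(fake))], as safe softplus terms."""
    loss = F.mean(F.softplus(fake_logits))  # -E[log(1-D(fake))]
    for rl in real_logit_maps:
        loss = loss + F.mean(F.softplus(F.mul(rl, -1.0)))  # -E[log D(real)]
    return loss


def generator_adversarial_t(fake_logits: Tensor, non_saturating: bool = False) -> Tensor:
    """The generator's adversarial term.

    Literal form: E[log(1-D(fake))] = -E[softplus(z)], minimized directly.
    Non-saturating form: -E[log D(fake)] = E[softplus(-z)].
    """
    if non_saturating:
        return F.mean(F.softplus(F.mul(fake_logits, -1.0)))
    return F.mul(F.mean(F.softplus(fake_logits)), -1.0)


def pixel_loss_t(y: Tensor, y_hat: Tensor) -> Tensor:
    if y.data.shape != y_hat.data.shape:
        raise ValueError("shape mismatch")
    return F.mean(F.absolute(y - y_hat))
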