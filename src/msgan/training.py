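"""Seeded adversarial training loop and subject-level cross-validation.

Each batch takes one discriminator step (minimizing the negated
adversarial value, i.e. maximizing it) followed by one generator step
(minimizing its adversarial term plus lambda times the L1 pixel loss),
both with Adam.  The learning rate follows a cosine annealing schedule
evaluated per epoch.  Single-channel MR slices are replicated across the
three model input channels at batch-assembly time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from . import objectives as obj
from .data_io import MultiSequenceSample
from .discriminator import DiscriminatorConfig, PatchDiscriminator, build_patch_discriminator
from .generator import Generator, GeneratorConfig, build_generator
from .nn import Adam, Tensor
from .nn import functional as F


@dataclass
class TrainConfig:
    epochs: int = 120
    batch_size: int = 64
    lr0: float = 2e-4
    lr_min: float = 0.0
    betas: tuple[float, float] = (0.5, 0.999)
    lambda_pix: float = 100.0
    seed: int = 0
    image_side: int = 256
    adversarial_mode: str = "literal"   # "literal" | "non_saturating"
    device: str = "cpu"
    checkpoint_every: Optional[int] = None
    checkpoint_dir: Optional[str] = None
    #: subjects reserved for a final held-out test, never entering CV folds
    holdout_subjects: tuple[str, ...] = ()

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr0 > self.lr_min >= 0:
            raise ValueError("need lr0 > lr_min >= 0")
        if self.adversarial_mode not in ("literal", "non_saturating"):
            raise ValueError(f"unknown adversarial mode {self.adversarial_mode!r}")


@dataclass
class CVSplit:
    assignment: dict[str, int]
    k: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def make_cv_splits(subject_ids: Sequence[str], k: int, seed: int) -> CVSplit:
    """Seeded shuffle then round-robin: subject-level folds of near-equal size."""
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"too many folds: k={k} > {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(j)]: i % k for i, j in enumerate(order)}
    return CVSplit(assignment=assignment, k=k)


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float = 0.0) -> float:
    if total_steps < 1 or not 0 <= step <= total_steps:
        raise ValueError(f"schedule overrun: step {step} outside [0, {total_steps}]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * step / total_steps))


def _stack_channels(img: np.ndarray, channels: int) -> np.ndarray:
    """Replicate a grayscale slice across the model's input channels."""
    return np.repeat(img[None], channels, axis=0)


def samples_to_arrays(samples: Sequence[MultiSequenceSample], channels: int = 3):
    x1 = np.stack([_stack_channels(s.x1, channels) for s in samples]).astype(np.float32)
    x2 = np.stack([_stack_channels(s.x2, channels) for s in samples]).astype(np.float32)
    y = np.stack([_stack_channels(s.y, channels) for s in samples]).astype(np.float32)
    return x1, x2, y


def _d_inputs(disc: PatchDiscriminator, candidate: Tensor, target: Tensor) -> Tensor:
    if disc.config.mode == "paired":
        return F.concat([candidate, target], axis=1)
    return candidate


def generate(gen: Generator, samples: Sequence[MultiSequenceSample]) -> list[np.ndarray]:
    """Evaluation-mode forward over samples; returns 2-D generated slices."""
    c = gen.config.in_channels
    x1, x2, _ = samples_to_arrays(samples, c)
    was_training = gen.training
    gen.eval()
    out = gen(Tensor(x1), None if gen.config.single_input_mode else Tensor(x2))
    gen.train(was_training)
    return [img.mean(axis=0) for img in out.data]  # average replicated channels


def train(gen: Generator, disc: PatchDiscriminator,
          samples: Sequence[MultiSequenceSample], config: TrainConfig,
          max_steps: Optional[int] = None) -> TrainHistory:
    """Alternating D/G updates over seeded-shuffled batches."""
    if len(samples) == 0:
        raise ValueError("no data")
    channels = gen.config.in_channels
    x1_all, x2_all, y_all = samples_to_arrays(samples, channels)
    n = len(samples)
    rng = np.random.default_rng(config.seed)
    g_opt = Adam(gen.parameters(), lr=config.lr0, betas=config.betas)
    d_opt = Adam(disc.parameters(), lr=config.lr0, betas=config.betas)
    single = gen.config.single_input_mode
    non_sat = config.adversarial_mode == "non_saturating"
    history = TrainHistory()
    gen.train()
    disc.train()

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    step = 0
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr0, config.lr_min)
        g_opt.lr = d_opt.lr = lr
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x1 = Tensor(x1_all[idx])
            x2 = Tensor(x2_all[idx])
            y = Tensor(y_all[idx])

            fake = gen(x1, None if single else x2)

            # -- discriminator step (fake detached) -----------------------
            d_opt.zero_grad()
            real_maps = [disc(_d_inputs(disc, x1, y))]
            if not single and disc.config.mode == "paired":
                real_maps.append(disc(_d_inputs(disc, x2, y)))
            fake_map_d = disc(_d_inputs(disc, Tensor(fake.data), y))
            d_loss = obj.discriminator_loss_t(real_maps, fake_map_d)
            d_loss.backward()
            d_opt.step()

            # -- generator step -------------------------------------------
            g_opt.zero_grad()
            fake_map_g = disc(_d_inputs(disc, fake, y))
            adv_t = obj.generator_adversarial_t(fake_map_g, non_saturating=non_sat)
            pix_t = obj.pixel_loss_t(y, fake)
            total_t = adv_t + F.mul(pix_t, config.lambda_pix)
            total_t.backward()
            g_opt.step()

            adv_v, pix_v = float(adv_t.data), float(pix_t.data)
            rec = {"step": step, "epoch": epoch, "lr": lr,
                   "adv": adv_v, "pix": pix_v,
                   "total": adv_v + config.lambda_pix * pix_v,
                   "d_loss": float(d_loss.data), "mode": disc.config.mode}
            if not all(math.isfinite(rec[k]) for k in ("adv", "pix", "total", "d_loss")):
                raise RuntimeError(f"diverged at step {step}")
            history.records.append(rec)
            step += 1

            if ckpt_dir and config.checkpoint_every and step % config.checkpoint_every == 0:
                path = ckpt_dir / f"gen_step{step:06d}.npz"
                gen.save(path)
                history.checkpoints.append(str(path))
            if max_steps is not None and step >= max_steps:
                if ckpt_dir:
                    final = ckpt_dir / "gen_final.npz"
                    gen.save(final)
                    history.checkpoints.append(str(final))
                return history
    if ckpt_dir:
        final = ckpt_dir / "gen_final.npz"
        gen.save(final)
        history.checkpoints.append(str(final))
    return history


@dataclass
class FoldResult:
    fold: int
    train_subjects: list[str]
    eval_subjects: list[str]
    report: metrics_mod.MetricReport
    history: TrainHistory

    def metric_means(self) -> dict[str, float]:
        s = self.report.summary()
        return {m: s[m]["mean"] for m in ("nmse", "rmse", "psnr", "ssim")}


def run_cv_experiment(subject_samples: dict[str, list[MultiSequenceSample]],
                      config: TrainConfig,
                      gen_config: Optional[GeneratorConfig] = None,
                      disc_config: Optional[DiscriminatorConfig] = None,
                      k: int = 5,
                      max_steps: Optional[int] = None) -> list[FoldResult]:
    """Train one model per fold on its training portion, evaluate on the rest."""
    cv_ids = sorted(set(subject_samples) - set(config.holdout_subjects))
    split = make_cv_splits(cv_ids, k, config.seed)
    subject_samples = {sid: subject_samples[sid] for sid in cv_ids}
    gen_config = gen_config or GeneratorConfig()
    results = []
    for fold in range(k):
        eval_ids = split.fold_subjects(fold)
        train_ids = sorted(set(subject_samples) - set(eval_ids))
        train_samples = [s for sid in train_ids for s in subject_samples[sid]]
        eval_samples = [s for sid in eval_ids for s in subject_samples[sid]]
        gen = build_generator(gen_config, seed=config.seed + fold)
        disc = build_patch_discriminator(disc_config, seed=config.seed + fold)
        history = train(gen, disc, train_samples, config, max_steps=max_steps)
        y_hat = generate(gen, eval_samples)
        report = metrics_mod.evaluate_batch(
            [(s.y, yh) for s, yh in zip(eval_samples, y_hat)],
            provenance=[{"subject_id": s.subject_id, "slice_index": s.slice_index}
                        for s in eval_samples])
        results.append(FoldResult(fold=fold, train_subjects=train_ids,
                                  eval_subjects=eval_ids, report=report,
                                  history=history))
    return results


def fold_metric_table(results: Sequence[FoldResult]) -> dict[str, list[float]]:
    """Per-metric list of fold means, in fold order."""
    table: dict[str, list[float]] = {m: [] for m in ("nmse", "rmse", "psnr", "ssim")}
    for res in results:
        for m, v in res.metric_means().items():
            table[m].append(v)
    return table
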