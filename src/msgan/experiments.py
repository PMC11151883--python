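"""Frozen desk-scale experiment protocols.

These are the study conditions the package's verification runs use: a
256x256 architecture trace, a short overfitting run on a tiny phantom
corpus, a paired dual-input vs single-input comparison on phantoms whose
target genuinely requires both sequences, and a family-wise error
calibration of the Dunnett procedure under a simulated global null.
Problem sizes are chosen so every protocol completes in minutes on one CPU
core; see docs/methods.md for the rationale behind each setting.
"""

from __future__ import annotations

import numpy as np

from .discriminator import DiscriminatorConfig, build_patch_discriminator
from .generator import GeneratorConfig, build_generator, trace_shapes
from .metrics import evaluate_batch
from .phantoms import PhantomSpec, generate_dataset
from .stats import dunnett_critical_value
from .training import TrainConfig, generate, train

#: overfitting smoke run: 8 slices, 64x64, 200 steps, half-width networks
SMOKE = dict(n_phantoms=8, canvas=64, steps=200, batch=8, base_channels=32)

#: dual-vs-single comparison: 32 slices (24 train / 8 held out), 150 steps,
#: quarter-width networks, five paired seeds
ADVANTAGE = dict(n_phantoms=32, n_train=24, canvas=64, steps=150, batch=8,
                 base_channels=16, n_seeds=5)


def trace_contract(side: int = 256) -> dict[str, tuple[int, int, int]]:
    """Named intermediate dimensions of the default generator at ``side``."""
    gen = build_generator(GeneratorConfig(), seed=0)
    return trace_shapes(gen, (3, side, side)).as_dict()


def overfit_smoke(seed: int = 0) -> dict[str, float]:
    """Short adversarial training on a tiny corpus; reports the pixel-loss
    drop from the initial plateau (mean of first 10 steps) to the final
    10-step mean."""
    p = SMOKE
    ds = generate_dataset(PhantomSpec(canvas_side=p["canvas"], seed=seed),
                          p["n_phantoms"])
    gen = build_generator(GeneratorConfig(base_channels=p["base_channels"]), seed=seed)
    disc = build_patch_discriminator(
        DiscriminatorConfig(base_channels=p["base_channels"]), seed=seed)
    cfg = TrainConfig(epochs=p["steps"], batch_size=p["batch"], seed=seed,
                      image_side=p["canvas"])
    history = train(gen, disc, ds.samples, cfg, max_steps=p["steps"])
    pix = [r["pix"] for r in history.records]
    first = float(np.mean(pix[:10]))
    last = float(np.mean(pix[-10:]))
    return {"pixel_loss_first10": first, "pixel_loss_last10": last,
            "ratio": last / first, "n_steps": len(pix)}


def _advantage_run(seed: int, single_input: bool) -> float:
    p = ADVANTAGE
    ds = generate_dataset(PhantomSpec(canvas_side=p["canvas"], seed=seed),
                          p["n_phantoms"])
    train_s, eval_s = ds.samples[:p["n_train"]], ds.samples[p["n_train"]:]
    gen = build_generator(
        GeneratorConfig(base_channels=p["base_channels"], single_input_mode=single_input),
        seed=seed)
    disc = build_patch_discriminator(
        DiscriminatorConfig(base_channels=p["base_channels"]), seed=seed)
    cfg = TrainConfig(epochs=p["steps"], batch_size=p["batch"], seed=seed,
                      image_side=p["canvas"])
    train(gen, disc, train_s, cfg, max_steps=p["steps"])
    y_hat = generate(gen, eval_s)
    report = evaluate_batch([(s.y, yh) for s, yh in zip(eval_s, y_hat)])
    return report.summary()["ssim"]["mean"]


def dual_vs_single(base_seed: int = 0) -> dict:
    """Held-out SSIM of the dual-encoder model vs the single-input variant
    over paired seeds, on phantoms whose target requires both inputs."""
    dual, single = [], []
    for s in range(ADVANTAGE["n_seeds"]):
        seed = base_seed + s
        dual.append(_advantage_run(seed, single_input=False))
        single.append(_advantage_run(seed, single_input=True))
    wins = sum(d > s for d, s in zip(dual, single))
    return {"dual_ssim": dual, "single_ssim": single, "wins": wins,
            "n_seeds": ADVANTAGE["n_seeds"]}


def dunnett_null_fwer(seed: int = 0, n_rep: int = 2000, n: int = 20,
                      k_treatments: int = 5, alpha: float = 0.05) -> dict:
    """Family-wise error rate of the Dunnett procedure under a simulated
    global null (all groups from one normal)."""
    crit = dunnett_critical_value(n, [n] * k_treatments,
                                  df=(k_treatments + 1) * (n - 1),
                                  alpha=alpha, n_mc=100_000, seed=seed)
    rng = np.random.default_rng(seed + 1)
    data = rng.normal(size=(n_rep, k_treatments + 1, n))
    means = data.mean(axis=2)
    ss = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
    pooled = ss / ((k_treatments + 1) * (n - 1))
    se = np.sqrt(pooled * (2.0 / n))
    t = np.abs(means[:, 1:] - means[:, :1]) / se[:, None]
    fwer = float((t.max(axis=1) > crit).mean())
    return {"fwer": fwer, "critical_value": crit, "n_rep": n_rep,
            "alpha": alpha, "k_treatments": k_treatments, "n_per_group": n}
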