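"""Cross-validation splitting, the learning-rate schedule and the train loop."""

import math

import numpy as np
import pytest

from msgan.discriminator import DiscriminatorConfig, build_patch_discriminator
from msgan.generator import GeneratorConfig, build_generator, load_generator
from msgan.phantoms import PhantomSpec, generate_dataset
from msgan.training import (TrainConfig, cosine_lr, fold_metric_table, generate,
                            make_cv_splits, run_cv_experiment, train)


class TestCVSplits:
    def test_even_partition(self):
        split = make_cv_splits([f"s{i}" for i in range(50)], 5, seed=0)
        sizes = [len(split.fold_subjects(f)) for f in range(5)]
        assert sizes == [10] * 5
        all_ids = [s for f in range(5) for s in split.fold_subjects(f)]
        assert len(set(all_ids)) == 50

    def test_pigeonhole_431_subjects(self):
        split = make_cv_splits([f"s{i}" for i in range(431)], 5, seed=1)
        sizes = sorted(len(split.fold_subjects(f)) for f in range(5))
        assert sizes == [86, 86, 86, 86, 87]

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(23)]
        a = make_cv_splits(ids, 5, seed=9).assignment
        b = make_cv_splits(ids, 5, seed=9).assignment
        assert a == b
        c = make_cv_splits(ids, 5, seed=10).assignment
        assert a != c

    def test_too_many_folds(self):
        with pytest.raises(ValueError, match="too many folds"):
            make_cv_splits(["a", "b"], 3, seed=0)


class TestCosineLR:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 100, 2e-4) == pytest.approx(2e-4)
        assert cosine_lr(100, 100, 2e-4) == pytest.approx(0.0, abs=1e-18)
        assert cosine_lr(50, 100, 2e-4, 1e-5) == pytest.approx((2e-4 + 1e-5) / 2)

    def test_overrun(self):
        with pytest.raises(ValueError, match="schedule overrun"):
            cosine_lr(101, 100, 2e-4)


def _tiny_setup(seed=0, single=False):
    spec = PhantomSpec(canvas_side=32, seed=seed)
    ds = generate_dataset(spec, 4)
    gen = build_generator(GeneratorConfig(base_channels=4, single_input_mode=single),
                          seed=seed)
    disc = build_patch_discriminator(DiscriminatorConfig(base_channels=4), seed=seed)
    cfg = TrainConfig(epochs=4, batch_size=4, seed=seed, image_side=32)
    return gen, disc, ds, cfg


class TestTrainLoop:
    def test_empty_dataset_rejected(self):
        gen, disc, _, cfg = _tiny_setup()
        with pytest.raises(ValueError, match="no data"):
            train(gen, disc, [], cfg)

    def test_seeded_runs_have_identical_trajectories(self):
        hists = []
        for _ in range(2):
            gen, disc, ds, cfg = _tiny_setup(seed=2)
            hists.append(train(gen, disc, ds.samples, cfg, max_steps=4))
        for r1, r2 in zip(hists[0].records, hists[1].records):
            assert r1 == r2

    def test_logged_lr_matches_schedule_and_total_identity(self):
        gen, disc, ds, cfg = _tiny_setup(seed=1)
        history = train(gen, disc, ds.samples, cfg)
        assert len(history.records) == 4  # one batch per epoch
        for rec in history.records:
            assert rec["lr"] == cosine_lr(rec["epoch"], cfg.epochs, cfg.lr0, cfg.lr_min)
            assert rec["total"] == pytest.approx(
                rec["adv"] + cfg.lambda_pix * rec["pix"], abs=1e-6)

    def test_checkpoint_roundtrip_preserves_outputs(self, tmp_path):
        gen, disc, ds, cfg = _tiny_setup(seed=3)
        cfg.checkpoint_dir = str(tmp_path)
        train(gen, disc, ds.samples, cfg, max_steps=3)
        reloaded = load_generator(tmp_path / "gen_final.npz")
        np.testing.assert_array_equal(
            np.stack(generate(gen, ds.samples)),
            np.stack(generate(reloaded, ds.samples)))

    def test_single_input_mode_trains(self):
        gen, disc, ds, cfg = _tiny_setup(seed=4, single=True)
        history = train(gen, disc, ds.samples, cfg, max_steps=2)
        assert all(math.isfinite(r["total"]) for r in history.records)

    def test_history_jsonl(self, tmp_path):
        gen, disc, ds, cfg = _tiny_setup(seed=5)
        history = train(gen, disc, ds.samples, cfg, max_steps=2)
        path = tmp_path / "log.jsonl"
        history.write_jsonl(path)
        assert len(path.read_text().strip().splitlines()) == 2


@pytest.fixture(scope="module")
def cv_results():
    subject_samples = {}
    for s in range(4):
        ds = generate_dataset(PhantomSpec(canvas_side=32, seed=100 + s), 2)
        samples = [type(x)(x1=x.x1, x2=x.x2, y=x.y, subject_id=f"subj{s}",
                           slice_index=x.slice_index, modalities=x.modalities)
                   for x in ds.samples]
        subject_samples[f"subj{s}"] = samples
    cfg = TrainConfig(epochs=1, batch_size=4, seed=0, image_side=32)
    results = run_cv_experiment(subject_samples, cfg,
                                GeneratorConfig(base_channels=4),
                                DiscriminatorConfig(base_channels=4),
                                k=2, max_steps=1)
    return subject_samples, results


class TestCrossValidation:
    def test_fold_structure(self, cv_results):
        _, results = cv_results
        assert len(results) == 2
        table = fold_metric_table(results)
        assert set(table) == {"nmse", "rmse", "psnr", "ssim"}
        assert all(len(v) == 2 for v in table.values())

    def test_no_subject_in_both_portions(self, cv_results):
        _, results = cv_results
        for res in results:
            assert not set(res.train_subjects) & set(res.eval_subjects)

    def test_eval_covers_all_subjects_once(self, cv_results):
        subject_samples, results = cv_results
        seen = [s for res in results for s in res.eval_subjects]
        assert sorted(seen) == sorted(subject_samples)


def test_holdout_subjects_never_enter_cv(cv_results):
    subject_samples, _ = cv_results
    cfg = TrainConfig(epochs=1, batch_size=4, seed=0, image_side=32,
                      holdout_subjects=("subj0",))
    results = run_cv_experiment(subject_samples, cfg,
                                GeneratorConfig(base_channels=4),
                                DiscriminatorConfig(base_channels=4),
                                k=2, max_steps=1)
    for res in results:
        assert "subj0" not in res.train_subjects
        assert "subj0" not in res.eval_subjects
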