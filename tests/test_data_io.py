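"""NIfTI subject loading, lesion-slice selection, normalization, padding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msgan.data_io import (MultiSequenceSample, NormalizationConfig, load_brats_subject,
                           make_samples, normalize_slice, pad_to_canvas,
                           save_samples_png, select_lesion_slices)
from msgan.phantoms import PhantomSpec, export_brats_subject, generate_dataset


@pytest.fixture(scope="module")
def mini_subject_dir(tmp_path_factory):
    spec = PhantomSpec(canvas_side=32, seed=4)
    root = tmp_path_factory.mktemp("subjects")
    return export_brats_subject(spec, 8, root, subject_id="mini"), spec


def test_roundtrip_load(mini_subject_dir):
    path, _ = mini_subject_dir
    subj = load_brats_subject(path, expected_shape=(32, 32, 8))
    assert subj.subject_id == "mini"
    assert set(subj.volumes) == {"T1", "T2", "FLAIR", "T1CE"}
    assert subj.seg.shape == (32, 32, 8)
    assert (subj.seg > 0).any()


def test_missing_sequence_is_incomplete_subject(tmp_path, mini_subject_dir):
    import shutil

    path, _ = mini_subject_dir
    broken = tmp_path / "broken"
    shutil.copytree(path, broken)
    (broken / "mini_flair.nii.gz").unlink()
    with pytest.raises(FileNotFoundError, match="incomplete subject"):
        load_brats_subject(broken)


def test_shape_mismatch_is_misaligned(tmp_path, mini_subject_dir):
    import shutil

    import nibabel as nib

    path, _ = mini_subject_dir
    broken = tmp_path / "misaligned"
    shutil.copytree(path, broken)
    nib.save(nib.Nifti1Image(np.zeros((16, 16, 4), dtype=np.int16), np.eye(4)),
             broken / "mini_seg.nii.gz")
    with pytest.raises(ValueError, match="misaligned volumes"):
        load_brats_subject(broken)


class TestSelectLesionSlices:
    def test_no_lesion_gives_empty(self):
        assert select_lesion_slices(np.zeros((8, 8, 5), dtype=int), 1) == []

    def test_contiguous_block_by_construction(self):
        seg = np.zeros((32, 32, 100), dtype=int)
        seg[10:20, 10:20, 60:81] = 1
        assert select_lesion_slices(seg, 1) == list(range(60, 81))

    def test_threshold_filters_small_lesions(self):
        seg = np.zeros((16, 16, 10), dtype=int)
        seg.reshape(-1, 10)[:50, 3] = 1   # 50 voxels in slice 3
        seg.reshape(-1, 10)[:200, 7] = 2  # 200 voxels in slice 7
        assert select_lesion_slices(seg, 100) == [7]

    def test_negative_labels_rejected(self):
        seg = np.zeros((4, 4, 2), dtype=int)
        seg[0, 0, 0] = -1
        with pytest.raises(ValueError, match="invalid segmentation"):
            select_lesion_slices(seg, 1)

    @settings(max_examples=25, derandomize=True)
    @given(thr_lo=st.integers(1, 30), thr_delta=st.integers(0, 30),
           seed=st.integers(0, 100))
    def test_monotone_in_threshold(self, thr_lo, thr_delta, seed):
        rng = np.random.default_rng(seed)
        seg = (rng.random((10, 10, 12)) < 0.15).astype(int)
        loose = set(select_lesion_slices(seg, thr_lo))
        strict = set(select_lesion_slices(seg, thr_lo + thr_delta))
        assert strict <= loose


class TestNormalizeSlice:
    def test_constant_slice_maps_to_zero(self):
        np.testing.assert_array_equal(normalize_slice(np.full((6, 6), 7.0)),
                                      np.zeros((6, 6)))

    def test_window_endpoints_map_to_unit_interval_ends(self):
        img = np.array([[0.0, 100.0], [100.0, 0.0]])
        out = normalize_slice(img, window=(0.0, 100.0))
        assert set(np.unique(out)) == {-1.0, 1.0}

    def test_output_range_contract(self, rng):
        out = normalize_slice(rng.normal(50, 20, (20, 20)))
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_nonfinite_rejected(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="invalid intensities"):
            normalize_slice(img)


class TestPadToCanvas:
    def test_240_to_256_has_8px_margins(self):
        out = pad_to_canvas(np.ones((240, 240)), 256, pad_value=-1.0)
        assert out.shape == (256, 256)
        assert (out[8:248, 8:248] == 1).all()
        assert (out[:8] == -1).all() and (out[:, :8] == -1).all()

    def test_identity_when_already_canvas(self):
        img = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(pad_to_canvas(img, 4), img)

    def test_cannot_pad_down(self):
        with pytest.raises(ValueError, match="cannot pad down"):
            pad_to_canvas(np.ones((300, 300)), 256)


class TestMakeSamples:
    def test_counts_and_provenance(self, mini_subject_dir):
        path, _ = mini_subject_dir
        subj = load_brats_subject(path)
        samples = make_samples(subj, ("T1", "T2"), "T1CE", [2, 3])
        assert len(samples) == 2
        assert [s.slice_index for s in samples] == [2, 3]
        assert all(s.subject_id == "mini" for s in samples)

    def test_duplicate_modalities_rejected(self, mini_subject_dir):
        path, _ = mini_subject_dir
        subj = load_brats_subject(path)
        with pytest.raises(ValueError, match="invalid pair"):
            make_samples(subj, ("T1", "T1"), "T1CE", [0])

    def test_unknown_sequence_rejected(self, mini_subject_dir):
        path, _ = mini_subject_dir
        subj = load_brats_subject(path)
        with pytest.raises(KeyError, match="unknown sequence"):
            make_samples(subj, ("T1", "DWI"), "T1CE", [0])

    def test_empty_slice_list_gives_empty_result(self, mini_subject_dir):
        path, _ = mini_subject_dir
        subj = load_brats_subject(path)
        assert make_samples(subj, ("T1", "T2"), "T1CE", []) == []

    def test_roundtrip_matches_direct_phantom_samples(self, mini_subject_dir):
        """Phantom -> NIfTI -> loader reproduces the direct phantom samples
        up to the export quantization."""
        path, spec = mini_subject_dir
        direct = generate_dataset(spec, 8).samples
        subj = load_brats_subject(path)
        norm = NormalizationConfig(window=(0.0, 10000.0))
        loaded = make_samples(subj, ("T1", "T2"), "T1CE", range(8), norm=norm)
        for d, l in zip(direct, loaded):
            np.testing.assert_allclose(l.x1, d.x1, atol=2.0 / 10000)
            np.testing.assert_allclose(l.y, d.y, atol=2.0 / 10000)


def test_sample_range_invariant_enforced():
    good = np.zeros((4, 4))
    with pytest.raises(ValueError, match="outside"):
        MultiSequenceSample(x1=good, x2=good, y=good + 2.0, subject_id="s",
                            slice_index=0, modalities=("T1", "T2"))


def test_png_export_writes_manifest(tmp_path, phantom_dataset):
    manifest = save_samples_png(phantom_dataset.samples[:2], tmp_path / "png")
    assert manifest.exists()
    import json

    records = json.loads(manifest.read_text())
    assert len(records) == 2
    assert (tmp_path / "png" / records[0]["files"]["y"]).exists()
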