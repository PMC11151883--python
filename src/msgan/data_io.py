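"""Reading BraTS-style multi-sequence subjects and preparing model samples.

A subject is a directory of co-registered NIfTI volumes, one per MR
sequence (T1, T2, FLAIR, T1CE) plus an integer tumor-segmentation label
volume, discovered by configurable filename suffixes.  Axial slices that
contain enough labelled lesion voxels are selected, normalized per slice
into [-1, 1] (the range the generator's Tanh head emits) and zero-padded
onto a square canvas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

SEQUENCE_NAMES = ("T1", "T2", "FLAIR", "T1CE")

#: BraTS2021 filename suffix conventions (matched against the file stem).
DEFAULT_SUFFIXES = {"T1": "_t1", "T2": "_t2", "FLAIR": "_flair", "T1CE": "_t1ce",
                    "seg": "_seg"}


@dataclass
class SubjectVolumes:
    subject_id: str
    volumes: dict[str, np.ndarray]
    seg: np.ndarray

    def __post_init__(self):
        shapes = {name: v.shape for name, v in self.volumes.items()}
        shapes["seg"] = self.seg.shape
        if len(set(shapes.values())) != 1:
            raise ValueError(f"misaligned volumes: {shapes}")


@dataclass
class MultiSequenceSample:
    """One aligned training triple: two input slices and the enhanced target."""

    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray
    subject_id: str
    slice_index: int
    modalities: tuple[str, str]

    def __post_init__(self):
        if not (self.x1.shape == self.x2.shape == self.y.shape):
            raise ValueError("sample channels must share one spatial shape")
        for name, img in (("x1", self.x1), ("x2", self.x2), ("y", self.y)):
            if img.min() < -1.0 - 1e-6 or img.max() > 1.0 + 1e-6:
                raise ValueError(f"{name} outside [-1, 1]")
        if self.modalities[0] == self.modalities[1]:
            raise ValueError("invalid pair: input modalities must be distinct")


@dataclass
class NormalizationConfig:
    """Per-slice intensity windowing before the affine map to [-1, 1].

    By default the window is the [lo_pct, hi_pct] percentile range of the
    slice's nonzero voxels (robust to scanner-scale outliers); an explicit
    absolute ``window`` overrides the percentiles, for data whose intensity
    scale is known.
    """

    lo_pct: float = 1.0
    hi_pct: float = 99.0
    window: Optional[tuple[float, float]] = None


def _stem(path: Path) -> str:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return path.stem


def load_brats_subject(path, expected_shape: Optional[tuple[int, int, int]] = None,
                       suffixes: Optional[dict[str, str]] = None) -> SubjectVolumes:
    """Load one subject directory of four sequence volumes plus segmentation."""
    path = Path(path)
    suffixes = dict(DEFAULT_SUFFIXES if suffixes is None else suffixes)
    nifti_files = sorted(list(path.glob("*.nii")) + list(path.glob("*.nii.gz")))
    found: dict[str, Path] = {}
    for key, suffix in suffixes.items():
        matches = [f for f in nifti_files if _stem(f).lower().endswith(suffix.lower())]
        if len(matches) == 1:
            found[key] = matches[0]
    missing = [k for k in suffixes if k not in found]
    if missing:
        raise FileNotFoundError(f"incomplete subject {path.name}: missing {missing}")

    arrays = {k: np.asanyarray(nib.load(f).dataobj) for k, f in found.items()}
    seg = np.asanyarray(arrays.pop("seg"))
    shapes = {k: a.shape for k, a in arrays.items()} | {"seg": seg.shape}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"misaligned volumes in {path.name}: {shapes}")
    if expected_shape is not None and seg.shape != tuple(expected_shape):
        raise ValueError(
            f"misaligned volumes: expected {tuple(expected_shape)}, got {seg.shape}")
    return SubjectVolumes(subject_id=path.name,
                          volumes={k: np.asarray(a, dtype=np.float64) for k, a in arrays.items()},
                          seg=seg)


def select_lesion_slices(seg: np.ndarray, min_lesion_pixels: int = 1) -> list[int]:
    """Axial slice indices with at least ``min_lesion_pixels`` labelled voxels."""
    seg = np.asarray(seg)
    if not np.issubdtype(seg.dtype, np.integer):
        if not np.all(seg == np.round(seg)):
            raise ValueError("invalid segmentation: labels must be integers")
        seg = seg.astype(np.int64)
    if seg.min() < 0:
        raise ValueError("invalid segmentation: labels must be non-negative")
    if min_lesion_pixels < 1:
        raise ValueError("min_lesion_pixels must be >= 1")
    counts = (seg > 0).sum(axis=(0, 1))
    return [int(i) for i in np.nonzero(counts >= min_lesion_pixels)[0]]


def normalize_slice(slice_img: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0,
                    window: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Window a slice and map it affinely to [-1, 1]; constant slices map to 0."""
    arr = np.asarray(slice_img, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("invalid intensities: non-finite values")
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
    else:
        nonzero = arr[arr != 0]
        ref = nonzero if nonzero.size else arr
        lo, hi = np.percentile(ref, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(arr)
    clipped = np.clip(arr, lo, hi)
    return 2.0 * (clipped - lo) / (hi - lo) - 1.0


def pad_to_canvas(image: np.ndarray, side: int, pad_value: float = -1.0) -> np.ndarray:
    """Center the image on a side x side canvas (extra pixel goes bottom/right)."""
    h, w = image.shape
    if h > side or w > side:
        raise ValueError(f"cannot pad down: image {h}x{w} exceeds canvas {side}")
    top = (side - h) // 2
    left = (side - w) // 2
    return np.pad(image, ((top, side - h - top), (left, side - w - left)),
                  constant_values=pad_value)


def make_samples(subject: SubjectVolumes, input_modalities: Sequence[str], target: str,
                 slice_indices: Sequence[int],
                 norm: Optional[NormalizationConfig] = None,
                 canvas_side: Optional[int] = None,
                 pad_value: float = -1.0) -> list[MultiSequenceSample]:
    """Build one normalized, padded sample per selected axial slice."""
    norm = norm or NormalizationConfig()
    m1, m2 = input_modalities
    if m1 == m2 or target in (m1, m2):
        raise ValueError("invalid pair: modalities must be distinct and differ from target")
    for name in (m1, m2, target):
        if name not in subject.volumes:
            raise KeyError(f"unknown sequence {name!r}; have {sorted(subject.volumes)}")

    def prep(vol, idx):
        img = normalize_slice(vol[:, :, idx], norm.lo_pct, norm.hi_pct, norm.window)
        if canvas_side is not None:
            img = pad_to_canvas(img, canvas_side, pad_value)
        return img

    samples = []
    for idx in slice_indices:
        samples.append(MultiSequenceSample(
            x1=prep(subject.volumes[m1], idx),
            x2=prep(subject.volumes[m2], idx),
            y=prep(subject.volumes[target], idx),
            subject_id=subject.subject_id,
            slice_index=int(idx),
            modalities=(m1, m2),
        ))
    return samples


def save_samples_png(samples: Sequence[MultiSequenceSample], out_dir,
                     bit_depth: int = 16) -> Path:
    """Write samples as PNG triples plus a JSON manifest, for inspection."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    scale = 65535 if bit_depth == 16 else 255
    manifest = []
    for i, s in enumerate(samples):
        rec = {"index": i, "subject_id": s.subject_id, "slice_index": s.slice_index,
               "modalities": list(s.modalities), "files": {}}
        for channel, img in (("x1", s.x1), ("x2", s.x2), ("y", s.y)):
            fname = f"sample{i:04d}_{channel}.png"
            quantized = np.round((img + 1.0) / 2.0 * scale).astype(dtype)
            iio.imwrite(out_dir / fname, quantized)
            rec["files"][channel] = fname
        manifest.append(rec)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"
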