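"""Synthetic co-registered multi-sequence slice phantoms.

Each phantom is a nested-ellipse "brain" of discrete tissue classes plus
an elliptical lesion with a rim and a core.  Every MR sequence renders the
same class map through its own class -> mean-intensity lookup (plus
additive Gaussian noise), which emulates the one property the translation
model actually consumes: shared geometry with sequence-specific contrast.

The enhanced target follows a deterministic rule that *requires both*
input sequences: the base intensity is the mean of the two input maps'
class intensities, and an enhancement offset is added inside the lesion
core.  The default lookups make the lesion rim isointense with its
surroundings in the first sequence and the core isointense with the rim in
the second, so no function of either input alone can reproduce the target
— the ground truth for the multi-modal-beats-single-modal comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .data_io import MultiSequenceSample

RIM_CLASS = 4
CORE_CLASS = 5


@dataclass
class LesionSpec:
    """Rim ellipse (fractions of canvas side) with a concentric core."""

    center: tuple[float, float] = (0.62, 0.40)
    axes: tuple[float, float] = (0.11, 0.085)
    rotation: float = 0.5
    core_scale: float = 0.55
    rim_class: int = RIM_CLASS
    core_class: int = CORE_CLASS


def _default_intensity_map() -> dict[str, dict[int, float]]:
    # classes: 0 background, 1 outer tissue, 2 inner tissue, 3 ventricle,
    # 4 lesion rim, 5 lesion core.  Rim is invisible in T1 (isointense with
    # class 1); core is invisible in T2 (isointense with the rim).
    return {
        "T1": {0: 0.0, 1: 0.70, 2: 0.50, 3: 0.20, RIM_CLASS: 0.70, CORE_CLASS: 0.35},
        "T2": {0: 0.0, 1: 0.35, 2: 0.55, 3: 0.90, RIM_CLASS: 0.85, CORE_CLASS: 0.85},
        "FLAIR": {0: 0.0, 1: 0.40, 2: 0.60, 3: 0.15, RIM_CLASS: 0.90, CORE_CLASS: 0.80},
    }


@dataclass
class PhantomSpec:
    canvas_side: int = 64
    n_tissue_classes: int = 3
    intensity_map: dict[str, dict[int, float]] = field(default_factory=_default_intensity_map)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    enhancement: float = 0.35
    noise_sd: float = 0.03
    seed: int = 0
    modalities: tuple[str, str] = ("T1", "T2")
    target: str = "T1CE"

    def __post_init__(self):
        for seq, lut in self.intensity_map.items():
            for cls, v in lut.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"intensity mean out of [0,1]: {seq}[{cls}]={v}")
        if min(self.lesion.axes) <= 0:
            raise ValueError("lesion axes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomDataset:
    samples: list[MultiSequenceSample]
    spec: PhantomSpec
    truth: list[np.ndarray]


def _ellipse_mask(side: int, center, axes, rotation) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    u = cos_t * dr + sin_t * dc
    v = -sin_t * dr + cos_t * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _jittered_lesion(spec: PhantomSpec, rng: np.random.Generator) -> LesionSpec:
    les = spec.lesion
    center = (les.center[0] + rng.uniform(-0.04, 0.04),
              les.center[1] + rng.uniform(-0.04, 0.04))
    axes = tuple(a * rng.uniform(0.85, 1.15) for a in les.axes)
    rotation = les.rotation + rng.uniform(-0.6, 0.6)
    return replace(les, center=center, axes=axes, rotation=rotation)


def build_class_map(spec: PhantomSpec, lesion: LesionSpec) -> np.ndarray:
    """Nested-ellipse tissue labels, then the lesion rim and core on top."""
    side = spec.canvas_side
    cm = np.zeros((side, side), dtype=np.int64)
    center = (side / 2.0, side / 2.0)
    brain_axes = [(0.44, 0.40), (0.30, 0.26), (0.09, 0.06)]
    for cls in range(1, spec.n_tissue_classes + 1):
        ax = brain_axes[min(cls - 1, len(brain_axes) - 1)]
        cm[_ellipse_mask(side, center, (ax[0] * side, ax[1] * side), 0.15)] = cls

    lc = (lesion.center[0] * side, lesion.center[1] * side)
    la = (lesion.axes[0] * side, lesion.axes[1] * side)
    rim = _ellipse_mask(side, lc, la, lesion.rotation)
    lo = (lc[0] - la[0] < 0 or lc[1] - la[1] < 0
          or lc[0] + la[0] >= side or lc[1] + la[1] >= side)
    if lo:
        raise ValueError("lesion out of bounds")
    core = _ellipse_mask(side, lc, (la[0] * lesion.core_scale, la[1] * lesion.core_scale),
                         lesion.rotation)
    cm[rim] = lesion.rim_class
    cm[core] = lesion.core_class
    return cm


def _render(class_map: np.ndarray, lut: dict[int, float]) -> np.ndarray:
    out = np.zeros(class_map.shape, dtype=np.float64)
    for cls, v in lut.items():
        out[class_map == cls] = v
    return out


def render_target_truth(spec: PhantomSpec, class_map: np.ndarray,
                        enhanced: bool = True) -> np.ndarray:
    """Noiseless target in [0, 1]: mean of the two input lookups, plus the
    core enhancement offset when ``enhanced``."""
    m1, m2 = spec.modalities
    base = 0.5 * (_render(class_map, spec.intensity_map[m1])
                  + _render(class_map, spec.intensity_map[m2]))
    if enhanced:
        base = base + spec.enhancement * (class_map == spec.lesion.core_class)
    return np.clip(base, 0.0, 1.0)


def _to_model_range(img01: np.ndarray) -> np.ndarray:
    return 2.0 * np.clip(img01, 0.0, 1.0) - 1.0


def render_phantom_slice(spec: PhantomSpec, index: int):
    """Deterministic full render of one slice.

    Returns (class_map, renders, truth01) where ``renders`` maps every
    sequence name (inputs, extras, and the target) to its noisy [0, 1]
    image and ``truth01`` is the noiseless target.
    """
    rng = np.random.default_rng([spec.seed, index])
    lesion = _jittered_lesion(spec, rng)
    class_map = build_class_map(spec, lesion)
    truth01 = render_target_truth(spec, class_map)
    renders = {}
    for seq in sorted(spec.intensity_map):
        img = _render(class_map, spec.intensity_map[seq])
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        renders[seq] = np.clip(img, 0.0, 1.0)
    y = truth01.copy()
    if spec.noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, spec.noise_sd, y.shape), 0.0, 1.0)
    renders[spec.target] = y
    return class_map, renders, truth01


def generate_phantom(spec: PhantomSpec, index: int):
    """One co-registered sample plus its noiseless target (both in [-1, 1])."""
    _, renders, truth01 = render_phantom_slice(spec, index)
    m1, m2 = spec.modalities
    sample = MultiSequenceSample(
        x1=_to_model_range(renders[m1]),
        x2=_to_model_range(renders[m2]),
        y=_to_model_range(renders[spec.target]),
        subject_id=f"phantom-{spec.seed}",
        slice_index=index,
        modalities=(m1, m2),
    )
    return sample, _to_model_range(truth01)


def generate_dataset(spec: PhantomSpec, n: int) -> PhantomDataset:
    if n < 1:
        raise ValueError("empty dataset: n must be >= 1")
    samples, truths = [], []
    for i in range(n):
        s, t = generate_phantom(spec, i)
        samples.append(s)
        truths.append(t)
    return PhantomDataset(samples=samples, spec=spec, truth=truths)


def export_brats_subject(spec: PhantomSpec, n: int, out_dir,
                         subject_id: Optional[str] = None,
                         intensity_scale: float = 10000.0) -> Path:
    """Write n phantom slices as a thin BraTS-layout NIfTI mini-subject.

    Sequences are stored as uint16 in arbitrary scanner-like units
    (``intensity_scale`` == raw value of intensity 1.0); the segmentation
    labels the lesion rim (2) and core (1).
    """
    import nibabel as nib

    from .data_io import DEFAULT_SUFFIXES

    subject_id = subject_id or f"phantom-{spec.seed}"
    out = Path(out_dir) / subject_id
    out.mkdir(parents=True, exist_ok=True)
    side = spec.canvas_side
    seqs = sorted(spec.intensity_map) + [spec.target]
    vols = {seq: np.zeros((side, side, n), dtype=np.uint16) for seq in seqs}
    seg = np.zeros((side, side, n), dtype=np.int16)
    for i in range(n):
        class_map, renders, _ = render_phantom_slice(spec, i)
        for seq in seqs:
            vols[seq][:, :, i] = np.round(renders[seq] * intensity_scale).astype(np.uint16)
        seg[:, :, i][class_map == spec.lesion.rim_class] = 2
        seg[:, :, i][class_map == spec.lesion.core_class] = 1
    affine = np.eye(4)
    for seq in seqs:
        suffix = DEFAULT_SUFFIXES.get(seq, "_" + seq.lower())
        nib.save(nib.Nifti1Image(vols[seq], affine), out / f"{subject_id}{suffix}.nii.gz")
    nib.save(nib.Nifti1Image(seg, affine), out / f"{subject_id}_seg.nii.gz")
    return out
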