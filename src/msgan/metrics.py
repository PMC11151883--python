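"""Image-quality metrics: NMSE, RMSE, PSNR and SSIM, with batch evaluation.

Conventions (recorded in every report): metrics are computed on the [0, 1]
rescale of the [-1, 1] model range, applied identically to reference and
candidate; data range 1; NMSE normalizes the squared-error energy by the
reference image's energy; PSNR of identical images is +inf, flagged and
excluded from summary means.  SSIM uses an 11x11 Gaussian window
(sigma 1.5, k1 0.01, k2 0.03), population local statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

CONVENTIONS = {
    "rescale": "[-1,1] -> [0,1] affine, applied to both images",
    "data_range": 1.0,
    "nmse_normalizer": "squared Frobenius norm of the reference",
    "psnr_identical": "infinite, flagged, excluded from means",
}


def _check_shapes(y, y_hat):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def rescale_to_unit(img: np.ndarray) -> np.ndarray:
    """Affine map from the model's [-1, 1] range to [0, 1]."""
    return (np.asarray(img, dtype=np.float64) + 1.0) / 2.0


def nmse(y, y_hat) -> float:
    y, y_hat = _check_shapes(y, y_hat)
    denom = float((y * y).sum())
    if denom == 0.0:
        raise ValueError("undefined NMSE: all-zero reference")
    return float(((y - y_hat) ** 2).sum()) / denom


def rmse(y, y_hat) -> float:
    y, y_hat = _check_shapes(y, y_hat)
    return float(np.sqrt(((y - y_hat) ** 2).mean()))


def psnr(y, y_hat, data_range: float = 1.0) -> float:
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    y, y_hat = _check_shapes(y, y_hat)
    mse = float(((y - y_hat) ** 2).mean())
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def ssim(y, y_hat, sigma: float = 1.5, truncate: float = 3.5,
         k1: float = 0.01, k2: float = 0.03, data_range: float = 1.0) -> float:
    """Mean local structural similarity with a Gaussian window."""
    y, y_hat = _check_shapes(y, y_hat)
    win = 2 * int(truncate * sigma + 0.5) + 1
    if min(y.shape) < win:
        raise ValueError(f"window too large: image {y.shape} smaller than {win}x{win}")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    filt = lambda a: gaussian_filter(a, sigma=sigma, truncate=truncate)
    ux, uy = filt(y), filt(y_hat)
    vx = filt(y * y) - ux * ux
    vy = filt(y_hat * y_hat) - uy * uy
    vxy = filt(y * y_hat) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


@dataclass
class MetricReport:
    """Per-image quality metrics plus provenance and the conventions used."""

    frame: pd.DataFrame
    conventions: dict = field(default_factory=lambda: dict(CONVENTIONS))

    def __len__(self):
        return len(self.frame)

    def summary(self) -> dict:
        out = {}
        for col in ("nmse", "rmse", "ssim"):
            out[col] = {"mean": float(self.frame[col].mean()),
                        "sd": float(self.frame[col].std(ddof=1)) if len(self.frame) > 1 else 0.0}
        finite = self.frame.loc[np.isfinite(self.frame["psnr"]), "psnr"]
        out["psnr"] = {
            "mean": float(finite.mean()) if len(finite) else math.inf,
            "sd": float(finite.std(ddof=1)) if len(finite) > 1 else 0.0,
            "n_infinite_excluded": int(len(self.frame) - len(finite)),
        }
        return out

    def write(self, csv_path, summary_path=None) -> None:
        self.frame.to_csv(csv_path, index=False)
        if summary_path is not None:
            payload = {"summary": self.summary(), "conventions": self.conventions}
            with open(summary_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def evaluate_batch(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                   data_range: float = 1.0,
                   provenance: Optional[Sequence[dict]] = None,
                   model_range: bool = True) -> MetricReport:
    """Whole-image metrics for (reference, candidate) pairs.

    With ``model_range`` (default) the pairs are taken in [-1, 1] and
    rescaled to [0, 1] before metric computation.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs")
    rows = []
    for i, (y, y_hat) in enumerate(pairs):
        if model_range:
            y, y_hat = rescale_to_unit(y), rescale_to_unit(y_hat)
        p = psnr(y, y_hat, data_range)
        row = {"index": i, "nmse": nmse(y, y_hat), "rmse": rmse(y, y_hat),
               "psnr": p, "psnr_finite": math.isfinite(p),
               "ssim": ssim(y, y_hat, data_range=data_range)}
        if provenance is not None:
            row.update(provenance[i])
        rows.append(row)
    return MetricReport(frame=pd.DataFrame(rows))
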