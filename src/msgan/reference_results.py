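"""Published five-fold cross-validation image-quality results.

Per-fold NMSE, PSNR, RMSE and SSIM for six contrast-synthesis
configurations on brain-tumor MRI — the dual-input fusion model with three
input-sequence pairings and the single-input pix2pix baseline with each
sequence alone — as reported for full-scale training.  These serve as
worked-example inputs for the fold-summarization tables and as the
reference values desk-scale acceptance checks arithmetic against; they are
not reproducible targets for desk-scale training.

Note: four published Average cells differ slightly from the mean of their
published fold values (consistent with averaging of unrounded data, plus
one 0.04 arithmetic slip in the PSNR "Dual (T1 & FLAIR)" column); the
``published_average`` entries preserve the printed numbers verbatim.
"""

from __future__ import annotations

DUAL_T1_T2 = "Dual (T1 & T2)"
DUAL_T1_FLAIR = "Dual (T1 & FLAIR)"
DUAL_T2_FLAIR = "Dual (T2 & FLAIR)"
PIX2PIX_T1 = "Pix2pix (T1)"
PIX2PIX_T2 = "Pix2pix (T2)"
PIX2PIX_FLAIR = "Pix2pix (FLAIR)"

MODELS = (DUAL_T1_T2, DUAL_T1_FLAIR, DUAL_T2_FLAIR,
          PIX2PIX_T1, PIX2PIX_T2, PIX2PIX_FLAIR)

#: metric -> model -> five per-fold values, fold order 1..5
FOLD_VALUES: dict[str, dict[str, list[float]]] = {
    "nmse": {
        DUAL_T1_T2: [0.559, 0.527, 0.523, 0.519, 0.520],
        DUAL_T1_FLAIR: [0.615, 0.565, 0.569, 0.562, 0.560],
        DUAL_T2_FLAIR: [0.593, 0.527, 0.533, 0.541, 0.538],
        PIX2PIX_T1: [0.621, 0.562, 0.570, 0.608, 0.568],
        PIX2PIX_T2: [0.616, 0.551, 0.544, 0.542, 0.551],
        PIX2PIX_FLAIR: [0.641, 0.557, 0.570, 0.559, 0.585],
    },
    "psnr": {
        DUAL_T1_T2: [23.122, 23.582, 23.739, 23.803, 23.772],
        DUAL_T1_FLAIR: [22.424, 23.105, 23.047, 23.141, 23.180],
        DUAL_T2_FLAIR: [22.695, 23.561, 23.475, 23.441, 23.420],
        PIX2PIX_T1: [22.085, 22.867, 22.823, 22.270, 22.828],
        PIX2PIX_T2: [22.173, 22.962, 23.169, 23.119, 23.011],
        PIX2PIX_FLAIR: [21.817, 22.885, 22.739, 22.891, 22.603],
    },
    "rmse": {
        DUAL_T1_T2: [0.081, 0.077, 0.077, 0.076, 0.076],
        DUAL_T1_FLAIR: [0.089, 0.082, 0.083, 0.081, 0.082],
        DUAL_T2_FLAIR: [0.085, 0.077, 0.078, 0.079, 0.079],
        PIX2PIX_T1: [0.089, 0.082, 0.083, 0.088, 0.083],
        PIX2PIX_T2: [0.088, 0.081, 0.080, 0.079, 0.081],
        PIX2PIX_FLAIR: [0.091, 0.081, 0.083, 0.082, 0.085],
    },
    "ssim": {
        DUAL_T1_T2: [0.855, 0.856, 0.861, 0.861, 0.863],
        DUAL_T1_FLAIR: [0.856, 0.859, 0.859, 0.860, 0.860],
        DUAL_T2_FLAIR: [0.854, 0.860, 0.860, 0.861, 0.858],
        PIX2PIX_T1: [0.843, 0.847, 0.853, 0.850, 0.848],
        PIX2PIX_T2: [0.847, 0.850, 0.855, 0.851, 0.851],
        PIX2PIX_FLAIR: [0.838, 0.849, 0.848, 0.850, 0.850],
    },
}

#: metric -> model -> the Average value as printed
PUBLISHED_AVERAGE: dict[str, dict[str, float]] = {
    "nmse": {DUAL_T1_T2: 0.529, DUAL_T1_FLAIR: 0.574, DUAL_T2_FLAIR: 0.546,
             PIX2PIX_T1: 0.586, PIX2PIX_T2: 0.561, PIX2PIX_FLAIR: 0.582},
    "psnr": {DUAL_T1_T2: 23.604, DUAL_T1_FLAIR: 22.939, DUAL_T2_FLAIR: 23.318,
             PIX2PIX_T1: 22.574, PIX2PIX_T2: 22.887, PIX2PIX_FLAIR: 22.587},
    "rmse": {DUAL_T1_T2: 0.077, DUAL_T1_FLAIR: 0.083, DUAL_T2_FLAIR: 0.079,
             PIX2PIX_T1: 0.085, PIX2PIX_T2: 0.082, PIX2PIX_FLAIR: 0.084},
    "ssim": {DUAL_T1_T2: 0.859, DUAL_T1_FLAIR: 0.859, DUAL_T2_FLAIR: 0.859,
             PIX2PIX_T1: 0.848, PIX2PIX_T2: 0.851, PIX2PIX_FLAIR: 0.847},
}

#: (metric, model) cells whose printed Average is not the 3-dp rounding of
#: the printed fold values (see module docstring)
AVERAGE_DISCREPANCIES: dict[tuple[str, str], float] = {
    ("nmse", DUAL_T1_T2): 0.0006,
    ("rmse", DUAL_T2_FLAIR): 0.0006,
    ("psnr", PIX2PIX_T1): 0.0006,
    ("psnr", DUAL_T1_FLAIR): 0.0404,
}
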