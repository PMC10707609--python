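"""Published four-method MRD1 summary statistics.

Per-method summary moments (n, mean, SD in mm) from a clinical
method-comparison study of 56 eyes in which MRD1 was measured four ways:
manually with a penlight (average of three raters), by a deep-learning
model on IR images, and by manual image analysis of RGB and IR
photographs. These moments are the canonical worked example for the
moments-based statistics in :mod:`mrdeye.stats` — the full ANOVA,
Scheffe post hoc and Bland-Altman mean differences are recoverable from
them without raw per-eye data.
"""

from __future__ import annotations

# method -> (n, mean_mm, sd_mm)
FOUR_METHOD_SUMMARY: dict[str, tuple[int, float, float]] = {
    "manual": (56, 2.6404, 1.03859),
    "dl": (56, 2.8450, 1.07324),
    "ir": (56, 2.7839, 1.07560),
    "rgb": (56, 3.0737, 0.94669),
}

METHOD_LABELS = {
    "manual": "MRD1_manual",
    "dl": "MRD1_DL",
    "ir": "MRD1_IR_ImageJ",
    "rgb": "MRD1_RGB_ImageJ",
}
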