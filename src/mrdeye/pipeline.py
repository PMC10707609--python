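"""End-to-end batch run: simulate -> segment -> measure -> agree.

One call renders a synthetic cohort of IR eye images, measures each
through the full segmentation + geometry chain (that measured value
plays the role of the automated-device column), fills in the manual and
image-analysis method columns from the cohort simulator, applies the
exclusion filter and computes the agreement report. Everything lands on
disk — images, masks, per-eye measurements, the cohort CSV, the report
JSON, figures and a plain-text log — and is fully determined by the
persisted config (seed included), so a rerun reproduces the measurement
CSV byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import RunConfig
from .geometry import measure_image
from .stats import agreement_report, apply_exclusions
from .synthetic import (
    CohortSimSpec,
    SyntheticEyeSpec,
    _truncated_normal,
    generate_cohort,
    render_eye,
)

log = logging.getLogger("mrdeye")


def run_pipeline(config: RunConfig, measure_only_dir=None) -> dict:
    """Execute a full reproducible run; returns a summary dict.

    With ``measure_only_dir`` set, existing images in that directory are
    measured instead of rendering a synthetic cohort (the statistics
    stage is skipped unless a cohort CSV is present there).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out / "run.log")
    config.to_json(out / "config.json")

    if measure_only_dir is not None:
        return _measure_directory(Path(measure_only_dir), out, config)

    rng = np.random.default_rng(config.seed)
    cohort_spec = replace(config.cohort, n_eyes=config.n_eyes, seed=config.seed)
    truths = _truncated_normal(rng, cohort_spec.mrd1_mean_mm, cohort_spec.mrd1_sd_mm, config.n_eyes)

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    records = []
    measured = []
    for i, t in enumerate(truths):
        spec = SyntheticEyeSpec(
            px_per_mm=config.px_per_mm,
            upper_lid=replace(SyntheticEyeSpec().upper_lid, apex_offset_mm=float(t)),
            noise_sd=config.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = render_eye(spec)
        mio.write_image(img_dir / f"eye_{i:04d}.png", image)
        mio.write_mask(img_dir / f"eye_{i:04d}_mask.png", truth.truth_mask)
        m = measure_image(image, seg_params=config.segmentation, geom_params=config.geometry)
        measured.append(m)
        rec = {"eye_id": f"eye_{i:04d}", "true_mrd1_mm": float(t), **_flatten(m)}
        records.append(rec)
        if not m.ok:
            log.warning("eye_%04d: measurement failed: %s", i, m.error)
        for flag in m.qc_flags:
            log.info("eye_%04d: QC flag %s", i, flag)
    meas_df = pd.DataFrame(records)
    meas_df.to_csv(out / "measurements.csv", index=False, float_format="%.6f")

    # four-method cohort: the pipeline's own measurement is the DL column,
    # the other three arms come from the cohort error model on the same truths
    sim = generate_cohort(cohort_spec)
    table = sim.copy()
    table["true_mrd1_mm"] = truths
    for col in ("mrd1_manual", "mrd1_rgb", "mrd1_ir"):
        table[col] = table[col] - sim["true_mrd1_mm"] + truths
    table["mrd1_dl"] = [m.mrd1_mm if m.ok else np.nan for m in measured]
    mio.write_cohort(out / "cohort.csv", table)

    retained, report_excl = apply_exclusions(
        table, config.stats.reference_method, config.stats.max_discrepancy_mm
    )
    log.info("exclusions: %s; retained %d/%d", report_excl.counts, report_excl.n_retained, len(table))
    summary: dict = {
        "n_eyes": config.n_eyes,
        "n_retained": report_excl.n_retained,
        "exclusion_counts": {str(k): v for k, v in report_excl.counts.items()},
        "n_measurement_failures": int(sum(not m.ok for m in measured)),
    }
    if report_excl.n_retained >= 3:
        report = agreement_report(retained, loa_multiplier=config.stats.loa_multiplier)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str))
        from . import plots

        plots.save_all(retained, report, out / "plots")
        summary["anova_f"] = report.anova.f
        summary["anova_p"] = report.anova.p
        summary["report"] = str(out / "report.json")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _measure_directory(src: Path, out: Path, config: RunConfig) -> dict:
    images = sorted(p for p in src.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
                    and not p.stem.endswith("_mask"))
    if not images:
        raise FileNotFoundError(f"no PNG/TIFF images found in {src}")
    records = []
    for p in images:
        img = mio.read_image(p)
        mask_path = p.with_name(p.stem + "_mask.png")
        mask = mio.read_mask(mask_path) if mask_path.exists() else None
        m = measure_image(img, mask=mask, seg_params=config.segmentation,
                          geom_params=config.geometry)
        records.append({"eye_id": p.stem, **_flatten(m)})
        if not m.ok:
            log.warning("%s: measurement failed: %s", p.name, m.error)
    df = pd.DataFrame(records)
    df.to_csv(out / "measurements.csv", index=False, float_format="%.6f")
    return {"n_images": len(images), "n_failures": int((~df["ok"]).sum())}


def _flatten(m) -> dict:
    d = m.to_dict()
    fit = d.pop("pupil_fit", None)
    if fit:
        d.update({f"pupil_{k}": v for k, v in fit.items()})
    d["qc_flags"] = ";".join(d["qc_flags"])
    return d


def _setup_log(path: Path) -> None:
    for h in list(log.handlers):
        log.removeHandler(h)
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
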