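"""Synthetic IR-style eye renderer and multi-method cohort simulator.

The renderer produces the kind of single-eye near-infrared close-up a
desktop MRD1 device captures: a dark pupil disk inside a mid-gray iris
annulus, bright sclera filling the palpebral aperture between two lid
margins, skin everywhere else, an optional specular glint, and a bright
circular fiducial dot of known physical diameter (5 mm by default) placed
on the lower-lid skin for pixel-to-millimetre calibration. Every render
comes with its exact ground-truth label mask and MRD1, so the whole
measurement pipeline can be validated without patient data.

Geometry lives in a millimetre frame anchored at the image center, x to
the right and y *downward* (matching the row axis). Lid margins are
parabolas in that frame; MRD1 is, by construction, the upper-lid
parabola's apex offset above the pupil center at the pupil-center column,
positive when the margin sits above the center. A positive MRD1 therefore
means an open lid, zero or negative means the lid covers the pupil center
— the ptosis cases the downstream exclusion rules deal with.

The cohort simulator emulates the four-arm measurement design used in
clinical MRD1 method-comparison studies: each eye has one true MRD1 drawn
from a truncated normal (true MRD1 > 0), and each measurement method
reports truth + fixed method bias + zero-mean Gaussian error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ClosedApertureError
from .segmentation import SegmentationMask

METHODS = ("manual", "dl", "rgb", "ir")
METHOD_COLUMNS = {m: f"mrd1_{m}" for m in METHODS}


@dataclass
class LidCurve:
    """Parabolic lid margin in the mm frame.

    ``apex_offset_mm`` is the unsigned distance of the lid apex from the
    pupil center at the pupil-center column: above the center for the
    upper lid, below for the lower lid. For the upper lid the offset IS
    the ground-truth MRD1 (it may be zero or negative for a drooping
    lid). ``curvature_per_mm`` bends the margin away from the apex toward
    the lid corners.
    """

    apex_offset_mm: float
    curvature_per_mm: float

    def margin_y(self, x_mm: np.ndarray, pupil_center_mm: tuple[float, float], sign: int):
        """Margin y (mm, downward-positive) at columns ``x_mm``.

        ``sign`` is -1 for the upper lid (apex above center, margin drops
        toward the corners) and +1 for the lower lid.
        """
        px, py = pupil_center_mm
        return py + sign * self.apex_offset_mm - sign * self.curvature_per_mm * (x_mm - px) ** 2


@dataclass
class SyntheticEyeSpec:
    """Full parameterization of one rendered eye.

    Intensities are mean gray levels on the 0–255 scale and must satisfy
    pupil < iris < sclera for IR realism (validated; set
    ``enforce_ir_order=False`` to render deliberately unrealistic
    images). ``noise_sd`` is additive Gaussian noise in gray levels.
    """

    image_height_px: int = 480
    image_width_px: int = 640
    px_per_mm: float = 12.0
    pupil_center_mm: tuple[float, float] = (0.0, 0.0)
    pupil_radius_mm: float = 2.0
    iris_radius_mm: float = 5.9
    upper_lid: LidCurve = field(default_factory=lambda: LidCurve(3.0, 0.03))
    lower_lid: LidCurve = field(default_factory=lambda: LidCurve(5.0, 0.025))
    pupil_gray: float = 25.0
    iris_gray: float = 90.0
    sclera_gray: float = 230.0
    skin_gray: float = 150.0
    noise_sd: float = 0.0
    glint_center_offset_mm: tuple[float, float] | None = None
    glint_radius_mm: float = 0.3
    glint_gray: float = 250.0
    dot_center_mm: tuple[float, float] | None = (0.0, 8.5)
    dot_diameter_mm: float = 5.0
    dot_gray: float = 245.0
    seed: int = 0
    enforce_ir_order: bool = True

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0 or self.px_per_mm <= 0:
            raise ValueError("image dimensions and px_per_mm must be positive")
        if self.pupil_radius_mm <= 0 or self.iris_radius_mm <= 0:
            raise ValueError("radii must be positive")
        if self.pupil_radius_mm >= self.iris_radius_mm:
            raise ValueError("pupil_radius_mm must be smaller than iris_radius_mm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.enforce_ir_order and not (self.pupil_gray < self.iris_gray < self.sclera_gray):
            raise ValueError("IR intensity order requires pupil < iris < sclera")

    @property
    def true_mrd1_mm(self) -> float:
        return self.upper_lid.apex_offset_mm


@dataclass
class GroundTruthRecord:
    """Exact per-render ground truth used by validation tests."""

    true_mrd1_mm: float
    true_pupil_center_px: tuple[float, float]  # (row, col)
    true_pupil_radius_px: float
    true_px_per_mm: float
    truth_mask: SegmentationMask


def _mm_grids(spec: SyntheticEyeSpec) -> tuple[np.ndarray, np.ndarray]:
    cy = (spec.image_height_px - 1) / 2.0
    cx = (spec.image_width_px - 1) / 2.0
    rows = (np.arange(spec.image_height_px)[:, None] - cy) / spec.px_per_mm
    cols = (np.arange(spec.image_width_px)[None, :] - cx) / spec.px_per_mm
    return rows, cols  # y_mm (H,1), x_mm (1,W)


def render_eye(spec: SyntheticEyeSpec) -> tuple[np.ndarray, GroundTruthRecord]:
    """Render one eye image and its ground truth.

    Classes are drawn in occlusion order: the lid aperture clips iris and
    pupil, the glint alters only image intensity (its pixels keep the
    underlying anatomical label in the truth mask), and the calibration
    dot sits on the skin, outside the aperture, labelled background.

    Returns an 8-bit grayscale image and a :class:`GroundTruthRecord`.
    Deterministic for a fixed ``spec.seed``.
    """
    y_mm, x_mm = _mm_grids(spec)
    px, py = spec.pupil_center_mm

    upper_y = spec.upper_lid.margin_y(x_mm, spec.pupil_center_mm, sign=-1)
    lower_y = spec.lower_lid.margin_y(x_mm, spec.pupil_center_mm, sign=+1)
    if upper_y[0, _nearest_col(spec, px)] >= lower_y[0, _nearest_col(spec, px)]:
        raise ClosedApertureError(
            "closed aperture: upper and lower lid margins cross at the pupil column"
        )

    aperture = (y_mm > upper_y) & (y_mm < lower_y)
    r2 = (x_mm - px) ** 2 + (y_mm - py) ** 2
    iris = aperture & (r2 <= spec.iris_radius_mm**2)
    pupil = aperture & (r2 <= spec.pupil_radius_mm**2)

    labels = np.zeros((spec.image_height_px, spec.image_width_px), dtype=np.uint8)
    labels[aperture] = 1
    labels[iris] = 2
    labels[pupil] = 3

    image = np.full(labels.shape, spec.skin_gray, dtype=np.float64)
    image[aperture] = spec.sclera_gray
    image[iris] = spec.iris_gray
    image[pupil] = spec.pupil_gray

    if spec.dot_center_mm is not None:
        dx, dy = spec.dot_center_mm
        dot = (x_mm - dx) ** 2 + (y_mm - dy) ** 2 <= (spec.dot_diameter_mm / 2.0) ** 2
        if (dot & aperture).any():
            raise ValueError("calibration dot overlaps the lid aperture; move dot_center_mm")
        image[dot] = spec.dot_gray

    if spec.glint_center_offset_mm is not None:
        gx, gy = spec.glint_center_offset_mm
        glint = (x_mm - (px + gx)) ** 2 + (y_mm - (py + gy)) ** 2 <= spec.glint_radius_mm**2
        image[glint] = spec.glint_gray  # mask labels intentionally untouched

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    cy = (spec.image_height_px - 1) / 2.0
    cx = (spec.image_width_px - 1) / 2.0
    truth = GroundTruthRecord(
        true_mrd1_mm=spec.true_mrd1_mm,
        true_pupil_center_px=(cy + py * spec.px_per_mm, cx + px * spec.px_per_mm),
        true_pupil_radius_px=spec.pupil_radius_mm * spec.px_per_mm,
        true_px_per_mm=spec.px_per_mm,
        truth_mask=SegmentationMask(labels, provenance="truth"),
    )
    return image, truth


def _nearest_col(spec: SyntheticEyeSpec, x_mm: float) -> int:
    cx = (spec.image_width_px - 1) / 2.0
    return int(round(cx + x_mm * spec.px_per_mm))


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSimSpec:
    """Four-method measurement cohort generator settings.

    True MRD1 per eye is drawn from a normal truncated to (0, inf)
    (clinically, eyes with MRD1 <= 0 are excluded from method-comparison
    cohorts). Each method column is truth + its fixed bias + Gaussian
    error. Defaults place the truth distribution at the pooled clinical
    mean 2.84 +/- 1.04 mm and give the automated methods small positive
    offsets relative to the manual penlight method, with 0.30 mm
    measurement error per method. ``manual_replicates`` > 1 averages that
    many independent manual readings per eye, emulating multi-rater
    manual measurement.
    """

    n_eyes: int = 56
    mrd1_mean_mm: float = 2.84
    mrd1_sd_mm: float = 1.04
    biases_mm: dict[str, float] = field(
        default_factory=lambda: {"manual": 0.0, "dl": 0.205, "rgb": 0.433, "ir": 0.144}
    )
    error_sds_mm: dict[str, float] = field(
        default_factory=lambda: {m: 0.30 for m in METHODS}
    )
    manual_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be at least 2")
        if self.mrd1_sd_mm <= 0:
            raise ValueError("mrd1_sd_mm must be positive")
        for m in METHODS:
            if self.error_sds_mm.get(m, 0.0) < 0:
                raise ValueError(f"error sd for method {m!r} must be non-negative")
        if self.manual_replicates < 1:
            raise ValueError("manual_replicates must be >= 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Draw from N(mean, sd) truncated to (0, inf) by rejection."""
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, size=2 * (n - out.size) + 16)
        out = np.concatenate([out, draw[draw > 0]])
    return out[:n]


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a per-eye four-method measurement table.

    Returns a DataFrame with columns ``patient_id``, ``eye_side``,
    ``true_mrd1_mm``, ``mrd1_manual``, ``mrd1_dl``, ``mrd1_rgb``,
    ``mrd1_ir`` (all mm) and, when ``manual_replicates`` > 1, one
    ``mrd1_manual_r<i>`` column per replicate (the manual column is their
    mean). Two eyes per patient, sides alternating OD/OS. Reproducible
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truncated_normal(rng, spec.mrd1_mean_mm, spec.mrd1_sd_mm, spec.n_eyes)
    table: dict[str, object] = {
        "patient_id": [f"P{1 + i // 2:04d}" for i in range(spec.n_eyes)],
        "eye_side": ["OD" if i % 2 == 0 else "OS" for i in range(spec.n_eyes)],
        "true_mrd1_mm": truth,
    }
    for m in METHODS:
        bias = spec.biases_mm.get(m, 0.0)
        sd = spec.error_sds_mm.get(m, 0.0)
        if m == "manual" and spec.manual_replicates > 1:
            reps = np.stack(
                [
                    truth + bias + (rng.normal(0.0, sd, spec.n_eyes) if sd > 0 else 0.0)
                    for _ in range(spec.manual_replicates)
                ]
            )
            for i in range(spec.manual_replicates):
                table[f"mrd1_manual_r{i + 1}"] = reps[i]
            table[METHOD_COLUMNS[m]] = reps.mean(axis=0)
        else:
            err = rng.normal(0.0, sd, spec.n_eyes) if sd > 0 else np.zeros(spec.n_eyes)
            table[METHOD_COLUMNS[m]] = truth + bias + err
    return pd.DataFrame(table)


def render_cohort_images(
    specs: list[SyntheticEyeSpec], out_dir
) -> pd.DataFrame:
    """Render a list of eyes to disk: image PNGs, mask PNGs and a truth CSV.

    Files are ``eye_<i>.png`` / ``eye_<i>_mask.png``; the returned (and
    saved) truth table has one row per eye with the ground-truth MRD1,
    pupil geometry and scale.
    """
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        image, truth = render_eye(spec)
        img_path = out / f"eye_{i:04d}.png"
        mask_path = out / f"eye_{i:04d}_mask.png"
        mio.write_image(img_path, image)
        mio.write_mask(mask_path, truth.truth_mask)
        rows.append(
            {
                "eye_id": f"eye_{i:04d}",
                "image": img_path.name,
                "mask": mask_path.name,
                "true_mrd1_mm": truth.true_mrd1_mm,
                "true_pupil_row_px": truth.true_pupil_center_px[0],
                "true_pupil_col_px": truth.true_pupil_center_px[1],
                "true_pupil_radius_px": truth.true_pupil_radius_px,
                "px_per_mm": truth.true_px_per_mm,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "truth.csv", index=False)
    return df
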