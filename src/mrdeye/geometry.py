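"""Calibrated MRD1 geometry from a 4-class segmentation mask.

MRD1 (marginal reflex distance 1) is the vertical distance, in mm, from
the pupil center to the upper eyelid margin in primary gaze: positive
when the margin is above the center, negative when the lid droops past
it. The chain implemented here is

    pupil circle fit  ->  upper-lid margin row  ->  px/mm calibration
                      ->  signed MRD1

* The pupil center comes from an algebraic least-squares (Kasa) circle
  fit to the pupil component's boundary, not from the mask centroid: a
  drooping lid occludes the upper pupil and drags a centroid downward,
  while a circle fitted to the remaining arc stays put. Boundary pixels
  bordering the iris are preferred; pixels along a lid chord border
  background and are dropped, which is what makes the fit
  occlusion-tolerant.
* The margin is found by scanning the pupil-center column upward for the
  first background run of at least ``margin_run_px`` rows (single-pixel
  speckle is skipped), reported at sub-pixel resolution as the midpoint
  of the class transition.
* The pixel scale comes from a circular fiducial dot of known physical
  diameter (5 mm by default) printed on the lower-lid skin.

All rows/columns use the top-origin convention shared across the
package (row 0 at the top, y increasing downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import (
    CalibrationError,
    InsufficientBoundaryError,
    MarginNotFoundError,
    MrdeyeError,
    PupilNotFoundError,
)
from .segmentation import SegmentationMask, SegmentationParams, segment_ir_eye

MIN_BOUNDARY_POINTS = 6


@dataclass
class PupilFit:
    """Least-squares circle fit of the pupil boundary."""

    center_row_px: float
    center_col_px: float
    radius_px: float
    rms_residual_px: float
    n_boundary_points: int


@dataclass
class CalibrationScale:
    """Pixel-to-millimetre scale from the reference dot."""

    px_per_mm: float
    dot_center_px: tuple[float, float] | None = None
    dot_diameter_px: float | None = None
    nominal_dot_mm: float = 5.0


@dataclass
class GeometryParams:
    """Geometry-stage tunables.

    ``margin_run_px`` (default 3) is the number of consecutive background
    rows required before a row counts as the lid margin — it skips
    single-pixel label noise. Dot detection accepts one bright blob with
    circularity >= ``dot_circularity_min`` inside the area window
    (px^2).
    """

    margin_run_px: int = 3
    nominal_dot_mm: float = 5.0
    dot_circularity_min: float = 0.85
    dot_area_window_px: tuple[float, float] = (200.0, 50000.0)
    fallback_px_per_mm: float | None = None


def fit_circle_kasa(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float, float]:
    """Algebraic (Kasa) circle fit.

    Minimizes sum((x^2 + y^2 + D x + E y + F)^2) over the boundary
    coordinates via linear least squares and converts (D, E, F) back to
    center and radius. Returns (center_row, center_col, radius,
    rms_geometric_residual).
    """
    y = np.asarray(rows, dtype=np.float64)
    x = np.asarray(cols, dtype=np.float64)
    if y.size < 3:
        raise InsufficientBoundaryError(f"need >= 3 points for a circle fit, got {y.size}")
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cx**2 + cy**2
    if r2 <= 0:
        raise InsufficientBoundaryError("degenerate circle fit (non-positive radius)")
    r = float(np.sqrt(r2))
    resid = np.hypot(x - cx, y - cy) - r
    return float(cy), float(cx), r, float(np.sqrt(np.mean(resid**2)))


def _pupil_boundary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundary pixels of the largest pupil component, preferring the arc.

    The boundary is the set of pupil pixels 4-adjacent to a non-pupil
    pixel. Of those, pixels adjacent to iris (class 2) lie on the true
    pupil rim; pixels adjacent to background lie on a lid-occlusion chord
    and are excluded when enough rim pixels remain.
    """
    pupil = labels == 3
    if not pupil.any():
        raise PupilNotFoundError("mask has no pupil (class 3) pixels")
    lab, n = ndi.label(pupil)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        pupil = lab == (1 + int(np.argmax(sizes)))
    pupil = ndi.binary_fill_holes(pupil)
    interior = ndi.binary_erosion(pupil, border_value=0)
    boundary = pupil & ~interior
    near_iris = ndi.binary_dilation(labels == 2) & boundary
    use = near_iris if near_iris.sum() >= MIN_BOUNDARY_POINTS else boundary
    rows, cols = np.nonzero(use)
    return rows, cols


def fit_pupil_circle(mask: SegmentationMask) -> PupilFit:
    """Fit the pupil circle from the retained pupil component.

    Raises :class:`InsufficientBoundaryError` with fewer than 6 boundary
    points — too degenerate for a trustworthy center.
    """
    rows, cols = _pupil_boundary(mask.labels)
    if rows.size < MIN_BOUNDARY_POINTS:
        raise InsufficientBoundaryError(
            f"insufficient pupil boundary: {rows.size} points (< {MIN_BOUNDARY_POINTS})"
        )
    cy, cx, r, rms = fit_circle_kasa(rows, cols)
    # boundary pixel centers sit ~half a pixel inside the true edge
    return PupilFit(cy, cx, r + 0.5, rms, int(rows.size))


def find_upper_lid_margin(
    mask: SegmentationMask,
    pupil_center: tuple[float, float],
    margin_run_px: int = 3,
) -> tuple[float, set[str]]:
    """Locate the upper-lid margin row on the pupil-center column.

    Scans upward from the pupil-center row for the first row labelled
    background (class 0) that begins a run of at least ``margin_run_px``
    consecutive background rows; isolated background speckle is skipped.
    The returned row is sub-pixel: the midpoint between the last
    non-background row and the first background row of the accepted run.

    If the pupil-center pixel itself is background the lid covers the
    pupil center (the MRD1 <= 0 case): the scan then runs *downward* to
    the first non-background run and the ``lid-covers-pupil-center`` flag
    is set.

    Returns ``(margin_row_px, qc_flags)``.
    """
    labels = mask.labels
    h, w = labels.shape
    row0 = int(round(pupil_center[0]))
    col = int(round(pupil_center[1]))
    if not (0 <= row0 < h and 0 <= col < w):
        raise MarginNotFoundError("pupil center outside mask bounds")
    column = labels[:, col]
    flags: set[str] = set()

    def run_ok(r: int, want_bg: bool, direction: int) -> bool:
        seg = column[r : r + margin_run_px] if direction > 0 else column[max(0, r - margin_run_px + 1) : r + 1]
        if seg.size < margin_run_px:
            return True  # image edge counts as sustained
        return bool(np.all(seg == 0)) if want_bg else bool(np.all(seg != 0))

    if column[row0] == 0:
        flags.add("lid-covers-pupil-center")
        for r in range(row0 + 1, h):
            if column[r] != 0 and run_ok(r, want_bg=False, direction=1):
                return r - 0.5, flags
        raise MarginNotFoundError("no eye tissue found below a covered pupil center")

    for r in range(row0 - 1, -1, -1):
        if column[r] == 0 and run_ok(r, want_bg=True, direction=-1):
            return r + 0.5, flags
    raise MarginNotFoundError("margin not found: column above pupil center is never background")


def detect_calibration_dot(
    image: np.ndarray, params: GeometryParams | None = None
) -> CalibrationScale:
    """Find the circular reference dot and derive the pixel scale.

    The dot is a high-contrast printed circle of known diameter
    (``nominal_dot_mm``, default 5) on the lower-lid skin. Candidate
    blobs are bright connected components within the configured area
    window whose circularity 4*pi*A/P^2 meets the threshold; exactly one
    must match, otherwise :class:`CalibrationError` reports the candidate
    count and the caller may supply ``px_per_mm`` explicitly. The scale
    is the blob's equivalent-area diameter divided by the nominal
    diameter.
    """
    params = params or GeometryParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise CalibrationError("calibration failed: blank image", n_candidates=0)
    thr = lo + 0.75 * (hi - lo)
    lab = sk_label(img > thr)
    candidates = []
    for rp in regionprops(lab):
        if not (params.dot_area_window_px[0] <= rp.area <= params.dot_area_window_px[1]):
            continue
        perim = rp.perimeter_crofton
        if perim <= 0:
            continue
        circularity = 4.0 * np.pi * rp.area / perim**2
        if circularity >= params.dot_circularity_min:
            candidates.append(rp)
    if len(candidates) != 1:
        raise CalibrationError(
            f"calibration failed: {len(candidates)} circular dot candidates",
            n_candidates=len(candidates),
        )
    dot = candidates[0]
    diameter_px = float(2.0 * np.sqrt(dot.area / np.pi))
    return CalibrationScale(
        px_per_mm=diameter_px / params.nominal_dot_mm,
        dot_center_px=(float(dot.centroid[0]), float(dot.centroid[1])),
        dot_diameter_px=diameter_px,
        nominal_dot_mm=params.nominal_dot_mm,
    )


def compute_mrd1(
    pupil_center_row: float, lid_margin_row: float, scale: CalibrationScale
) -> tuple[float, float]:
    """Signed MRD1 from center row, margin row and scale.

    With the top-origin row convention, ``mrd1_px = center - margin`` is
    positive when the margin is above the center (open lid). Returns
    ``(mrd1_mm, mrd1_px)``.
    """
    if scale.px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    mrd1_px = float(pupil_center_row - lid_margin_row)
    return mrd1_px / scale.px_per_mm, mrd1_px


@dataclass
class Mrd1Measurement:
    """One eye's measurement with all intermediates and QC flags.

    ``ok`` is False for structured failures (no pupil, no margin, failed
    calibration without a fallback scale); ``error`` then holds the
    reason and the numeric fields are None. ``qc_flags`` accumulates
    soft warnings such as ``margin-below-center`` or ``no-dot``.
    """

    ok: bool
    mrd1_mm: float | None = None
    mrd1_px: float | None = None
    pupil_fit: PupilFit | None = None
    lid_margin_row_px: float | None = None
    scale: CalibrationScale | None = None
    qc_flags: set[str] = field(default_factory=set)
    error: str | None = None
    exclusion_rule: int | None = None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "ok": self.ok,
            "mrd1_mm": self.mrd1_mm,
            "mrd1_px": self.mrd1_px,
            "lid_margin_row_px": self.lid_margin_row_px,
            "qc_flags": sorted(self.qc_flags),
            "error": self.error,
            "exclusion_rule": self.exclusion_rule,
        }
        if self.pupil_fit is not None:
            d["pupil_fit"] = vars(self.pupil_fit)
        if self.scale is not None:
            d["px_per_mm"] = self.scale.px_per_mm
            d["dot_diameter_px"] = self.scale.dot_diameter_px
        return d


def measure_image(
    image: np.ndarray,
    mask: SegmentationMask | None = None,
    seg_params: SegmentationParams | None = None,
    geom_params: GeometryParams | None = None,
) -> Mrd1Measurement:
    """Full single-eye measurement: segment, fit, margin, calibrate, MRD1.

    Sub-operation failures are returned as a structured failure record,
    never raised: an unmeasurable eye is data (it maps to the cohort
    exclusion rule for machine failures), not a crash. When dot
    calibration fails but ``geom_params.fallback_px_per_mm`` is set, the
    fallback scale is used and the ``no-dot`` flag raised.
    """
    geom_params = geom_params or GeometryParams()
    flags: set[str] = set()
    try:
        if mask is None:
            mask = segment_ir_eye(image, seg_params)
        fit = fit_pupil_circle(mask)
        margin_row, margin_flags = find_upper_lid_margin(
            mask, (fit.center_row_px, fit.center_col_px), geom_params.margin_run_px
        )
        flags |= margin_flags
        if fit.n_boundary_points < 20:
            flags.add("low-boundary-count")
        try:
            scale = detect_calibration_dot(image, geom_params)
        except CalibrationError:
            if geom_params.fallback_px_per_mm is None:
                raise
            scale = CalibrationScale(px_per_mm=geom_params.fallback_px_per_mm)
            flags.add("no-dot")
        mrd1_mm, mrd1_px = compute_mrd1(fit.center_row_px, margin_row, scale)
        if mrd1_mm <= 0:
            flags.add("margin-below-center")
        return Mrd1Measurement(
            ok=True,
            mrd1_mm=mrd1_mm,
            mrd1_px=mrd1_px,
            pupil_fit=fit,
            lid_margin_row_px=margin_row,
            scale=scale,
            qc_flags=flags,
        )
    except (PupilNotFoundError, InsufficientBoundaryError) as e:
        # the "machine could not measure" case -> cohort exclusion rule 5
        return Mrd1Measurement(ok=False, error=str(e), qc_flags=flags, exclusion_rule=5)
    except (MarginNotFoundError, CalibrationError, MrdeyeError) as e:
        return Mrd1Measurement(ok=False, error=str(e), qc_flags=flags)
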