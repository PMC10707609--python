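"""Geometry-stage tests: circle fit, lid margin, calibration, MRD1."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrdeye import (
    CalibrationError,
    CalibrationScale,
    GeometryParams,
    InsufficientBoundaryError,
    LidCurve,
    MarginNotFoundError,
    SegmentationMask,
    SyntheticEyeSpec,
    compute_mrd1,
    detect_calibration_dot,
    find_upper_lid_margin,
    fit_circle_kasa,
    fit_pupil_circle,
    measure_image,
    render_eye,
)


def disk_mask(shape, center, radius, label=3, iris_pad=6):
    """Pupil disk wrapped in an iris annulus, on background."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    labels = np.zeros(shape, dtype=np.uint8)
    labels[d2 <= (radius + iris_pad) ** 2] = 2
    labels[d2 <= radius**2] = label
    return SegmentationMask(labels)


class TestCircleFit:
    def test_rasterized_disk_recovered(self):
        mask = disk_mask((480, 640), (200, 320), 24)
        fit = fit_pupil_circle(mask)
        assert fit.center_row_px == pytest.approx(200, abs=0.5)
        assert fit.center_col_px == pytest.approx(320, abs=0.5)
        assert fit.radius_px == pytest.approx(24, abs=0.5)

    def test_exact_circle_points_machine_precision(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        cy, cx, r = 101.25, 250.5, 33.7
        rows, cols = cy + r * np.sin(theta), cx + r * np.cos(theta)
        fy, fx, fr, resid = fit_circle_kasa(rows, cols)
        assert resid < 1e-9
        assert (fy, fx, fr) == pytest.approx((cy, cx, r), abs=1e-9)

    def test_occluded_disk_center_column_accurate(self, make_eye):
        # MRD1 1.0 mm < pupil radius 2 mm: the lid clips the upper pupil
        _, truth = make_eye(upper_lid=LidCurve(1.0, 0.03))
        fit = fit_pupil_circle(truth.truth_mask)
        assert abs(fit.center_col_px - truth.true_pupil_center_px[1]) < 1.0
        assert abs(fit.center_row_px - truth.true_pupil_center_px[0]) < 1.0

    def test_too_few_boundary_points(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[5, 5] = 3
        with pytest.raises(InsufficientBoundaryError):
            fit_pupil_circle(SegmentationMask(labels))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cy=st.floats(50, 400), cx=st.floats(50, 600), r=st.floats(5, 40),
        n=st.integers(20, 100),
    )
    def test_kasa_exact_on_analytic_circles(self, cy, cx, r, n):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        fy, fx, fr, resid = fit_circle_kasa(cy + r * np.sin(theta), cx + r * np.cos(theta))
        assert (fy, fx, fr) == pytest.approx((cy, cx, r), abs=1e-6)
        assert resid < 1e-6


class TestLidMargin:
    def make_column_mask(self, margin_offset=36, center=(200, 100)):
        labels = np.zeros((400, 200), dtype=np.uint8)
        labels[center[0] - margin_offset + 1 : center[0] + 60, :] = 1
        rr, cc = np.mgrid[:400, :200]
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        labels[(d2 <= 30**2) & (labels > 0)] = 2
        labels[(d2 <= 20**2) & (labels > 0)] = 3
        return SegmentationMask(labels)

    def test_margin_at_known_offset(self):
        mask = self.make_column_mask(margin_offset=36)
        row, flags = find_upper_lid_margin(mask, (200, 100))
        assert row == pytest.approx(200 - 36, abs=0.5)
        assert not flags

    def test_single_pixel_speckle_skipped(self):
        mask = self.make_column_mask(margin_offset=36)
        labels = mask.labels.copy()
        labels[190, 100] = 0  # 1-px background speckle 10 px above center
        row, _ = find_upper_lid_margin(SegmentationMask(labels), (200, 100))
        assert row == pytest.approx(200 - 36, abs=0.5)

    def test_lid_covering_center_flagged(self, make_eye):
        _, truth = make_eye(upper_lid=LidCurve(-1.0, 0.03))
        r, c = truth.true_pupil_center_px
        row, flags = find_upper_lid_margin(truth.truth_mask, (r, c))
        assert "lid-covers-pupil-center" in flags
        assert row > r  # margin below center -> negative MRD1

    def test_margin_not_found_on_full_column(self):
        labels = np.ones((50, 50), dtype=np.uint8)
        labels[20:30, 20:30] = 3
        labels[15:35, 15:35][labels[15:35, 15:35] != 3] = 2
        with pytest.raises(MarginNotFoundError):
            find_upper_lid_margin(SegmentationMask(labels), (25, 25))


class TestCalibrationDot:
    def test_rendered_dot_gives_scale(self, noiseless_eye):
        img, truth = noiseless_eye
        scale = detect_calibration_dot(img)
        assert scale.px_per_mm == pytest.approx(12.0, abs=0.2)
        assert scale.dot_diameter_px == pytest.approx(60.0, abs=1.0)

    def test_no_dot_fails(self, make_eye):
        img, _ = make_eye(dot_center_mm=None)
        with pytest.raises(CalibrationError) as exc:
            detect_calibration_dot(img)
        assert exc.value.n_candidates == 0

    def test_two_dots_fail_with_count(self, make_eye):
        img, _ = make_eye()
        img = img.copy()
        rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
        img[(rr - 60) ** 2 + (cc - 80) ** 2 <= 30**2] = 245  # second dot on skin
        with pytest.raises(CalibrationError) as exc:
            detect_calibration_dot(img)
        assert exc.value.n_candidates == 2


class TestComputeMrd1:
    @pytest.mark.parametrize(
        "center_row, margin_row, expected_mm",
        [(200.0, 164.0, 3.0), (200.0, 200.0, 0.0), (200.0, 212.0, -1.0)],
    )
    def test_arithmetic_and_sign(self, center_row, margin_row, expected_mm):
        scale = CalibrationScale(px_per_mm=12.0)
        mm, px = compute_mrd1(center_row, margin_row, scale)
        assert mm == pytest.approx(expected_mm)
        assert px == pytest.approx(expected_mm * 12.0)


class TestMeasureImage:
    def test_noiseless_recovers_truth_within_one_pixel(self, noiseless_eye):
        img, truth = noiseless_eye
        m = measure_image(img)
        assert m.ok
        assert abs(m.mrd1_mm - truth.true_mrd1_mm) <= 1.0 / truth.true_px_per_mm

    def test_negative_mrd1_returned_not_clamped(self, make_eye):
        img, truth = make_eye(upper_lid=LidCurve(-1.0, 0.03))
        m = measure_image(img, mask=truth.truth_mask)
        assert m.ok and m.mrd1_mm < 0
        assert {"margin-below-center", "lid-covers-pupil-center"} <= m.qc_flags

    def test_unmeasurable_image_gives_failure_record(self):
        m = measure_image(np.full((100, 100), 128, dtype=np.uint8))
        assert not m.ok
        assert m.exclusion_rule == 5
        assert m.mrd1_mm is None and m.error

    def test_fallback_scale_when_no_dot(self, make_eye):
        img, truth = make_eye(dot_center_mm=None)
        m = measure_image(img, geom_params=GeometryParams(fallback_px_per_mm=12.0))
        assert m.ok and "no-dot" in m.qc_flags
        assert m.mrd1_mm == pytest.approx(truth.true_mrd1_mm, abs=0.1)

    def test_scale_equivariance(self):
        results = {}
        for s in (8.0, 12.0, 16.0):
            img, _ = render_eye(replace(SyntheticEyeSpec(), px_per_mm=s))
            results[s] = measure_image(img).mrd1_mm
        vals = list(results.values())
        for s in results:
            assert max(vals) - min(vals) <= 2.0 / s

    def test_translation_invariance(self, make_eye):
        # whole-pixel shift: 0.5 mm at 12 px/mm = 6 px
        m0 = measure_image(make_eye()[0])
        m1 = measure_image(make_eye(pupil_center_mm=(0.5, 0.5), dot_center_mm=(0.5, 9.0))[0])
        assert abs(m0.mrd1_mm - m1.mrd1_mm) < 1e-6
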