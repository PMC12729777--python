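"""Orientation quantification: segmentation, ellipse fit, filament
detection, the orientation statistic and its invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytomech import orientation as oq
from cytomech import synthetic as syn
from cytomech.synthetic import CellImage


@pytest.fixture(scope="module")
def plain_cell():
    return syn.generate_cell_image(axis_angle=30.0, semi_major=100,
                                   semi_minor=40, noise_sd=0.0, seed=5)


class TestSegmentCell:
    def test_mask_area_matches_ellipse(self, plain_cell):
        img, truth = plain_cell
        mask, contour = oq.segment_cell(img)
        true_area = math.pi * truth.semi_major * truth.semi_minor
        assert abs(mask.sum() - true_area) / true_area < 0.02
        assert len(contour) >= 5

    def test_empty_scene_raises(self):
        with pytest.raises(oq.EmptySceneError):
            oq.segment_cell(CellImage(pixels=np.zeros((64, 64))))

    def test_largest_component_wins(self):
        px = np.zeros((200, 300))
        yy, xx = np.mgrid[0:200, 0:300]
        small = ((xx - 60) / 20) ** 2 + ((yy - 100) / 14) ** 2 <= 1
        big = ((xx - 200) / 28) ** 2 + ((yy - 100) / 20) ** 2 <= 1
        px[small] = 100.0
        px[big] = 100.0
        mask, contour = oq.segment_cell(CellImage(pixels=px), smooth_sigma=1.0)
        # contour encloses the larger ellipse (centred at x=200)
        assert abs(contour[:, 0].mean() - 200) < 5
        assert not mask[100, 60]


class TestFitLongAxis:
    def _ellipse_polygon(self, a, b, angle_deg, n=200):
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        th = math.radians(angle_deg)
        x = a * np.cos(t) * math.cos(th) - b * np.sin(t) * math.sin(th) + 150
        y = a * np.cos(t) * math.sin(th) + b * np.sin(t) * math.cos(th) + 150
        return np.column_stack([x, y])

    def test_exact_polygon_recovery(self):
        fit = oq.fit_long_axis(self._ellipse_polygon(100, 40, 30))
        assert fit.semi_major == pytest.approx(100, abs=1.0)
        assert fit.semi_minor == pytest.approx(40, abs=1.0)
        assert min(abs(fit.axis_angle - 30), 180 - abs(fit.axis_angle - 30)) < 1.0

    def test_circle_flagged_degenerate(self):
        fit = oq.fit_long_axis(self._ellipse_polygon(50, 50, 0))
        assert fit.degenerate

    def test_axis_is_undirected(self):
        p = self._ellipse_polygon(80, 30, 20)
        c = p.mean(axis=0)
        rotated = 2 * c - p  # 180 degree rotation about the centre
        f1 = oq.fit_long_axis(p)
        f2 = oq.fit_long_axis(rotated)
        assert f1.axis_angle == pytest.approx(f2.axis_angle, abs=1e-6)
        assert f1.semi_major == pytest.approx(f2.semi_major, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(oq.FitError):
            oq.fit_long_axis(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))


class TestDetectFilaments:
    def test_three_filaments_recovered_with_angles(self):
        img, truth = syn.generate_cell_image(
            axis_angle=0.0, filament_angles=[0.0, 45.0, 90.0],
            noise_sd=0.0, seed=8,
        )
        mask, _ = oq.segment_cell(img)
        segs = oq.detect_filaments(img, mask)
        assert len(segs) == 3
        found = sorted(min(s.direction_deg, 180 - s.direction_deg)
                       if s.direction_deg > 90 else s.direction_deg
                       for s in segs)
        for det, true in zip(found, [0.0, 45.0, 90.0]):
            assert abs(det - true) < 2.0

    def test_no_filaments_empty_list(self, plain_cell):
        img, _ = plain_cell
        mask, _ = oq.segment_cell(img)
        assert oq.detect_filaments(img, mask) == []

    def test_line_outside_mask_excluded(self):
        img, _ = syn.generate_cell_image(semi_major=60, semi_minor=30,
                                         noise_sd=0.0, seed=2)
        px = img.pixels.copy()
        px[10:13, 20:120] = 300.0  # bright bar far outside the cell
        img2 = CellImage(pixels=px)
        mask, _ = oq.segment_cell(img)
        assert oq.detect_filaments(img2, mask) == []


class TestFilamentAngle:
    @pytest.mark.parametrize("d,expected", [
        ((1, 0), 0.0), ((0, 1), 90.0), ((1, 1), 45.0),
    ])
    def test_reference_directions(self, d, expected):
        seg = oq.FilamentSegment((0.0, 0.0), (float(d[0]), float(d[1])))
        ell = oq.EllipseFit(center=(0, 0), semi_major=10, semi_minor=5,
                            axis_angle=0.0)
        assert oq.filament_angle(seg, ell) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            oq.FilamentSegment((1.0, 1.0), (1.0, 1.0))


class TestMeanOrientationValue:
    def test_parallel_is_one(self):
        assert oq.mean_orientation_value([0.0]) == 1.0

    def test_perpendicular_is_minus_one(self):
        assert oq.mean_orientation_value([90.0]) == -1.0

    def test_mean_45_is_zero(self):
        assert oq.mean_orientation_value([30.0, 60.0]) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            oq.mean_orientation_value([])
        with pytest.raises(ValueError):
            oq.mean_orientation_value([95.0])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 90), min_size=1, max_size=20))
    def test_formula_exact_and_linear(self, angles):
        v = oq.mean_orientation_value(angles)
        assert v == pytest.approx(1.0 - np.mean(angles) / 45.0, abs=1e-12)
        assert -1.0 <= v <= 1.0 + 1e-12
        # averaging order: mean of per-angle values equals value of mean
        per = [oq.mean_orientation_value([a]) for a in angles]
        assert np.mean(per) == pytest.approx(v, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 90))
    def test_antisymmetry_about_45(self, a):
        assert oq.mean_orientation_value([a]) + oq.mean_orientation_value([90 - a]) \
            == pytest.approx(0.0, abs=1e-12)


class TestQuantifyImage:
    @pytest.mark.parametrize("angles,target", [
        ([0.0, 0.0, 0.0], 1.0),
        ([90.0, 90.0, 90.0], -1.0),
        ([0.0, 90.0, 0.0, 90.0], 0.0),
    ])
    def test_value_recovery(self, angles, target):
        img, _ = syn.generate_cell_image(axis_angle=20.0,
                                         filament_angles=angles,
                                         noise_sd=0.0, seed=0)
        res = oq.quantify_image(img)
        assert res.n_filaments > 0
        assert abs(res.mean_orientation_value - target) < 0.07

    def test_rotation_equivariance(self):
        img, _ = syn.generate_cell_image(axis_angle=10.0,
                                         filament_angles=[30.0] * 3,
                                         noise_sd=0.0, seed=21)
        r0 = oq.quantify_image(img)
        r90 = oq.quantify_image(CellImage(pixels=np.rot90(img.pixels).copy()))
        assert abs(r0.mean_angle - r90.mean_angle) < 3.0

    def test_stage_error_labelled(self):
        with pytest.raises(oq.EmptySceneError, match="segment_cell"):
            oq.quantify_image(CellImage(pixels=np.zeros((32, 32))))
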