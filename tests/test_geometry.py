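"""Centroid, centerline, segment-selection and cutting-point geometry tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budcut.geometry import (
    EmptyRegionError,
    LineSegment,
    NoAxisError,
    NoBudError,
    PixelPoint,
    bud_centerline,
    cutting_point,
    detect_axis_segments,
    line_value,
    locate_cutting_point,
    point_segment_distance,
    region_centroid,
    select_axis_segment,
    split_upper_lower,
)
from budcut.synthetic import SceneParams, generate_scene

from oracles import centroid_brute_force, point_line_distance_closed_form


def seg(x1, y1, x2, y2):
    return LineSegment(PixelPoint(x1, y1), PixelPoint(x2, y2))


class TestRegionCentroid:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[7, 5] = 1
        c = region_centroid(mask)
        assert (c.x, c.y) == (5, 7)

    def test_filled_rectangle_symmetry(self):
        mask = np.zeros((10, 20), dtype=np.uint8)
        mask[0:10, 0:20] = 1
        c = region_centroid(mask)
        assert (c.x, c.y) == (9.5, 4.5)

    def test_l_shape_matches_brute_force(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[2:10, 2:5] = 1
        mask[7:10, 2:11] = 1
        c = region_centroid(mask)
        ox, oy = centroid_brute_force(mask)
        assert c.x == pytest.approx(ox, abs=1e-12)
        assert c.y == pytest.approx(oy, abs=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            region_centroid(np.zeros((4, 4), dtype=np.uint8))

    def test_moment_additivity_over_halves(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((20, 20)) < 0.4).astype(np.uint8)
        mask[0, 0] = 1
        mask[19, 19] = 1
        upper, lower = split_upper_lower(mask)
        whole = region_centroid(mask)
        cu, cl = region_centroid(upper), region_centroid(lower)
        au, al = upper.sum(), lower.sum()
        assert whole.x == pytest.approx((cu.x * au + cl.x * al) / (au + al))
        assert whole.y == pytest.approx((cu.y * au + cl.y * al) / (au + al))


class TestSplitUpperLower:
    def test_rectangle_split_rows(self):
        mask = np.zeros((12, 8), dtype=np.uint8)
        mask[0:10] = 1
        upper, lower = split_upper_lower(mask)
        assert upper[0:5].all() and not upper[5:].any()
        assert lower[5:10].all() and not lower[0:5].any()

    def test_symmetric_ellipse_balanced(self):
        yy, xx = np.mgrid[0:40, 0:40]
        mask = (((xx - 20) / 15.0) ** 2 + ((yy - 20) / 10.0) ** 2 <= 1).astype(np.uint8)
        upper, lower = split_upper_lower(mask)
        row = mask[20].sum()
        assert abs(int(upper.sum()) - int(lower.sum())) <= row

    def test_partition_identity(self):
        rng = np.random.default_rng(9)
        mask = (rng.random((15, 15)) < 0.5).astype(np.uint8)
        mask[3, 3] = 1
        upper, lower = split_upper_lower(mask)
        assert np.array_equal(upper | lower, mask)
        assert not (upper & lower).any()

    def test_single_row_goes_to_upper(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[2, 1:5] = 1
        upper, lower = split_upper_lower(mask)
        assert upper.sum() == 4 and lower.sum() == 0


class TestBudCenterline:
    def test_vertically_symmetric_bud_zero_delta(self):
        yy, xx = np.mgrid[0:60, 0:40]
        mask = (((xx - 20) / 8.0) ** 2 + ((yy - 30) / 20.0) ** 2 <= 1).astype(np.uint8)
        _, delta = bud_centerline(mask)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_two_pixel_closed_form(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[0, 0] = 1
        mask[4, 3] = 1
        pair, delta = bud_centerline(mask)
        assert (pair.upper.x, pair.upper.y) == (0, 0)
        assert (pair.lower.x, pair.lower.y) == (3, 4)
        assert delta == pytest.approx(math.degrees(math.atan(3 / 4)), abs=1e-9)

    def test_rotated_fixture_recovers_tilt(self):
        # slender superellipse rotated by a known angle about its center
        true_tilt = 15.0
        d = math.radians(true_tilt)
        yy, xx = np.mgrid[0:200, 0:200].astype(float)
        ux, uy = math.sin(d), -math.cos(d)
        u = (xx - 100) * ux + (yy - 100) * uy
        v = (xx - 100) * (-uy) + (yy - 100) * ux
        mask = ((np.abs(u / 60) ** 3 + np.abs(v / 17) ** 3) <= 1).astype(np.uint8)
        _, delta = bud_centerline(mask)
        assert delta == pytest.approx(true_tilt, abs=2.0)


class TestLineValue:
    def test_zero_on_endpoints_and_midpoint(self):
        s = seg(1, 2, 7, 10)
        assert line_value(s, s.p1) == 0
        assert line_value(s, PixelPoint(4, 6)) == 0

    def test_hand_evaluated_example(self):
        assert line_value(seg(1, 0, 1, 2), PixelPoint(0, 0)) == -2


class TestPointSegmentDistance:
    def test_point_on_line_zero(self):
        assert point_segment_distance(PixelPoint(4, 6), seg(1, 2, 7, 10)) == 0

    def test_unit_offset_vertical_line(self):
        assert point_segment_distance(PixelPoint(0, 0), seg(1, 0, 1, 2)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x1, y1, x2, y2, px, py = rng.uniform(-50, 50, 6)
        if (x1, y1) == (x2, y2):
            return
        got = point_segment_distance(PixelPoint(px, py), seg(x1, y1, x2, y2))
        want = point_line_distance_closed_form(px, py, x1, y1, x2, y2)
        assert got == pytest.approx(want, abs=1e-9)

    @given(
        st.integers(-30, 30), st.integers(-30, 30), st.integers(-30, 30),
        st.integers(-30, 30), st.integers(-30, 30), st.integers(-30, 30),
        st.integers(-10, 10), st.integers(-10, 10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_translation_and_swap_invariance(self, x1, y1, x2, y2, px, py, tx, ty):
        if (x1, y1) == (x2, y2):
            return
        s = seg(x1, y1, x2, y2)
        p = PixelPoint(px, py)
        d = point_segment_distance(p, s)
        shifted = point_segment_distance(
            PixelPoint(px + tx, py + ty), seg(x1 + tx, y1 + ty, x2 + tx, y2 + ty)
        )
        swapped = point_segment_distance(p, seg(x2, y2, x1, y1))
        assert d == pytest.approx(shifted, abs=1e-9)
        assert d == pytest.approx(swapped, abs=1e-9)
        # algebraic identity with the cross-product form
        assert d * s.length == pytest.approx(abs(line_value(s, p)), abs=1e-9)


class TestSelectAxisSegment:
    def test_single_segment(self):
        s = seg(0, 0, 0, 10)
        best, dist = select_axis_segment([s], PixelPoint(3, 5))
        assert best == s and dist == 3

    def test_two_parallel_segments(self):
        near, far = seg(2, 0, 2, 10), seg(7, 0, 7, 10)
        best, dist = select_axis_segment([far, near], PixelPoint(0, 5))
        assert best == near and dist == 2

    def test_exhaustive_argmin_over_random_segments(self):
        rng = np.random.default_rng(4)
        segments = []
        while len(segments) < 10:
            x1, y1, x2, y2 = rng.uniform(0, 100, 4)
            if (x1, y1) != (x2, y2):
                segments.append(seg(x1, y1, x2, y2))
        c = PixelPoint(50, 50)
        best, dist = select_axis_segment(segments, c)
        dists = [point_segment_distance(c, s) for s in segments]
        assert dist == pytest.approx(min(dists), abs=1e-12)
        assert point_segment_distance(c, best) == dist

    def test_empty_list_raises(self):
        with pytest.raises(NoAxisError):
            select_axis_segment([], PixelPoint(0, 0))


class TestCuttingPoint:
    @pytest.mark.parametrize(
        "segment, expected",
        [
            (((0, 0), (10, 10)), (5, 5)),
            (((2, 3), (2, 9)), (2, 6)),
            (((0, 0), (3, 0)), (2, 0)),  # 1.5 rounds half away from zero
        ],
    )
    def test_midpoint_rounding(self, segment, expected):
        (x1, y1), (x2, y2) = segment
        p = cutting_point(seg(x1, y1, x2, y2))
        assert (p.x, p.y) == expected


class TestDetectAxisSegments:
    def test_vertical_strip_midline(self):
        mask = np.zeros((100, 60), dtype=np.uint8)
        mask[10:91, 28:32] = 1  # 4-px-wide strip, rows 10..90
        segments = detect_axis_segments(mask)
        assert segments
        good = [
            s
            for s in segments
            if point_segment_distance(PixelPoint(29.5, 50), s) <= 3
            and abs(s.p2.y - s.p1.y) >= 0.6 * 81
        ]
        assert good

    def test_empty_mask(self):
        assert detect_axis_segments(np.zeros((20, 20), dtype=np.uint8)) == []

    def test_tilted_strip_angle(self):
        d = math.radians(20)
        yy, xx = np.mgrid[0:120, 0:120].astype(float)
        x0, y0 = 60, 110
        dx, dy = math.sin(d), -math.cos(d)
        t = np.clip((xx - x0) * dx + (yy - y0) * dy, 0, 90)
        dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
        mask = (dist <= 2.0).astype(np.uint8)
        segments = detect_axis_segments(mask)
        assert segments
        best = max(segments, key=lambda s: s.length)
        angle_from_vertical = math.degrees(
            math.atan2(abs(best.p2.x - best.p1.x), abs(best.p2.y - best.p1.y))
        )
        assert angle_from_vertical == pytest.approx(20, abs=3)


class TestLocateCuttingPoint:
    def test_vertical_scene_cut_near_truth_and_apex(self):
        truth = generate_scene(SceneParams(tilt_delta=0.0, seed=5))
        res = locate_cutting_point(truth.image)
        err = math.hypot(
            res.cut_point.x - truth.true_cut_point.x,
            res.cut_point.y - truth.true_cut_point.y,
        )
        assert err < 15
        apex_x = truth.params.bud_apex()[0]
        assert abs(res.cut_point.x - apex_x) <= 3

    def test_tilted_scene_within_tolerance(self):
        truth = generate_scene(SceneParams(tilt_delta=20.0, seed=6))
        res = locate_cutting_point(truth.image)
        err = math.hypot(
            res.cut_point.x - truth.true_cut_point.x,
            res.cut_point.y - truth.true_cut_point.y,
        )
        assert err < 15

    def test_vertical_scene_line_passes_near_centroid(self):
        truth = generate_scene(SceneParams(tilt_delta=0.0, seed=5))
        res = locate_cutting_point(truth.image)
        assert not res.fallback
        assert point_segment_distance(res.bud_centroid, res.selected_segment) <= 2

    def test_blank_image_raises_no_bud(self):
        with pytest.raises(NoBudError):
            locate_cutting_point(np.zeros((64, 64, 3), dtype=np.uint8))
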