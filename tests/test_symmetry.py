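import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from limbsym import (
    DEFAULT_PALETTE,
    ClassPalette,
    LabelImage,
    SectionSpec,
    SymmetryWindow,
    ToleranceSpec,
    WindowSpec,
    class_mask,
    contour_axis_points,
    extract_window,
    generate_label_section,
    place_axis,
    refine_angle,
    score_sample,
    score_window,
)
from limbsym.symmetry import _rotate_point, _rotate_raster, _rotated_frame
from oracle_utils import brute_force_scores

# toy classes: muscle=3, cartilage=2, epidermis=5
M, C, E = 3, 2, 5


def _blank(h, w, fill=1):
    return LabelImage(np.full((h, w), fill, np.uint8), DEFAULT_PALETTE, 1.0)


class TestPlaceAxis:
    def test_vertical_segment_needs_no_rotation(self):
        axis = place_axis(_blank(100, 100), (10, 50), (90, 50))
        assert axis.rotation_deg == 0.0
        assert axis.mirror_row == 50.0

    def test_horizontal_segment_rotates_quarter_turn(self):
        axis = place_axis(_blank(10, 120), (0, 0), (0, 100))
        assert axis.rotation_deg == 90.0
        rot, c_in, c_out, _ = _rotated_frame((10, 120), axis.rotation_deg)
        rd = _rotate_point((0, 0), rot, c_in, c_out)
        rv = _rotate_point((0, 100), rot, c_in, c_out)
        assert axis.mirror_row == pytest.approx((rd[0] + rv[0]) / 2)

    def test_oblique_segment_lands_on_one_column_dorsal_up(self):
        """Rotation oracle: the rotated endpoints share a column."""
        d, v = (10, 10), (90, 30)
        axis = place_axis(_blank(100, 100), d, v)
        assert axis.rotation_deg == pytest.approx(math.degrees(math.atan2(20, 80)))
        rot, c_in, c_out, _ = _rotated_frame((100, 100), axis.rotation_deg)
        rd = _rotate_point(d, rot, c_in, c_out)
        rv = _rotate_point(v, rot, c_in, c_out)
        assert rd[1] == pytest.approx(rv[1], abs=1e-9)
        assert rd[0] < rv[0]

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            place_axis(_blank(10, 10), (5, 5), (5, 5))

    def test_point_outside_raster_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            place_axis(_blank(10, 10), (-1, 0), (5, 5))


class TestWindowGeometry:
    def test_400um_at_4um_per_px_is_100_columns(self):
        assert WindowSpec(width_um=400).width_px(4.0) == 100

    def test_width_forced_even(self):
        # 400/3 = 133.3 px -> 134 (even)
        assert WindowSpec(width_um=400).width_px(3.0) == 134

    def test_subpixel_window_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 px"):
            WindowSpec(width_um=1.0).width_px(4.0)

    def test_symmetric_raster_gives_identical_halves(self, symmetric_section):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        win = extract_window(symmetric_section, axis)
        assert win.dorsal.shape == (128, 100)
        assert np.array_equal(win.dorsal, win.ventral_flipped)

    def test_center_row_excluded_when_mirror_row_is_integer(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(1, 6, (5, 4)).astype(np.uint8)
        lab = LabelImage(arr, DEFAULT_PALETTE, 1.0)
        axis = place_axis(lab, (0, 1), (4, 1))
        assert axis.mirror_row == 2.0
        win = extract_window(lab, axis, WindowSpec(center_col=1, width_um=2.0))
        assert win.dorsal.shape == (2, 2)
        assert np.array_equal(win.dorsal, arr[0:2, 0:2])
        assert np.array_equal(win.ventral_flipped, arr[3:5, 0:2][::-1])

    def test_out_of_bounds_window_rejected(self, symmetric_section):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        with pytest.raises(ValueError, match="outside the rotated raster"):
            extract_window(symmetric_section, axis, WindowSpec(center_col=10))


class TestClassMask:
    def test_label_domain_equality(self):
        half = np.array([[1, 2], [2, 5]], np.uint8)
        assert np.array_equal(class_mask(half, 2), half == 2)

    def test_rgb_all_three_channels_rule(self):
        px = np.array([[[110, 105, 95]], [[111, 100, 100]]], np.uint8)
        m = class_mask(px, (100, 100, 100), ToleranceSpec(10))
        assert m[0, 0] and not m[1, 0]

    def test_degenerate_tolerances(self, symmetric_section, clean_render):
        color = DEFAULT_PALETTE.color(3)
        exact = class_mask(clean_render.pixels, color, ToleranceSpec(0))
        assert np.array_equal(exact, symmetric_section.labels == 3)
        assert class_mask(clean_render.pixels, color, ToleranceSpec(255)).all()


class TestScoreWindow:
    def test_toy_worked_example(self):
        """2×4 window [M,C,C,M; E,E,E,C] mirrored between columns 1 and 2."""
        left = np.array([[M, C], [E, E]], np.uint8)
        right_flipped = np.array([[M, C], [C, E]], np.uint8)
        win = SymmetryWindow(left, right_flipped)
        res = score_window(win, DEFAULT_PALETTE)
        assert res.scores[M] == 1.0
        assert res.scores[C] == 0.5
        assert res.scores[E] == 0.5
        assert res.scores[1] is None and res.scores[4] is None
        assert res.combined == pytest.approx(0.6)

    def test_identical_halves_score_one(self):
        rng = np.random.default_rng(1)
        half = rng.integers(1, 6, (6, 6)).astype(np.uint8)
        res = score_window(SymmetryWindow(half, half.copy()), DEFAULT_PALETTE)
        assert all(s == 1.0 for s in res.scores.values() if s is not None)
        assert res.combined == 1.0

    def test_disjoint_halves_score_zero(self):
        a = np.full((3, 3), M, np.uint8)
        b = np.full((3, 3), C, np.uint8)
        res = score_window(SymmetryWindow(a, b), DEFAULT_PALETTE)
        assert res.scores[M] == 0.0 and res.scores[C] == 0.0
        assert res.combined == 0.0

    def test_sum_denominator_halves_a_perfect_mirror(self):
        half = np.full((4, 4), M, np.uint8)
        res = score_window(
            SymmetryWindow(half, half.copy()), DEFAULT_PALETTE, denominator="sum"
        )
        assert res.scores[M] == 0.5

    def test_rgb_domain_matches_label_domain_on_exact_render(
        self, symmetric_section, clean_render
    ):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        lab_win = extract_window(symmetric_section, axis)
        rgb_win = extract_window(clean_render, axis)
        a = score_window(lab_win, DEFAULT_PALETTE)
        b = score_window(rgb_win, DEFAULT_PALETTE, ToleranceSpec(0))
        assert a.scores == b.scores

    def test_empty_window_rejected(self):
        win = SymmetryWindow(np.zeros((0, 2), np.uint8), np.zeros((0, 2), np.uint8))
        with pytest.raises(ValueError, match="empty window"):
            score_window(win, DEFAULT_PALETTE)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            h, w = rng.integers(1, 9, 2)
            d = rng.integers(1, 6, (h, w)).astype(np.uint8)
            v = rng.integers(1, 6, (h, w)).astype(np.uint8)
            for denom in ("union", "sum"):
                res = score_window(SymmetryWindow(d, v), DEFAULT_PALETTE, denominator=denom)
                exp_scores, exp_combined = brute_force_scores(d, v, denominator=denom)
                assert res.scores == exp_scores
                assert res.combined == pytest.approx(exp_combined)


label_halves = hnp.arrays(
    np.uint8, st.tuples(st.integers(1, 6), st.integers(1, 6)),
    elements=st.integers(1, 5),
)


class TestScoreProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(label_halves, st.data())
    def test_range_mediant_and_half_swap(self, d, data):
        v = data.draw(
            hnp.arrays(np.uint8, d.shape, elements=st.integers(1, 5))
        )
        res = score_window(SymmetryWindow(d, v), DEFAULT_PALETTE)
        defined = [s for s in res.scores.values() if s is not None]
        for c, s in res.scores.items():
            if s is not None:
                assert 0.0 <= s <= 1.0
                assert res.matching[c] <= res.total[c]
        assert min(defined) - 1e-12 <= res.combined <= max(defined) + 1e-12
        swapped = score_window(SymmetryWindow(v, d), DEFAULT_PALETTE)
        assert swapped.scores == res.scores
        assert swapped.combined == res.combined

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(label_halves, st.permutations([1, 2, 3, 4, 5]))
    def test_palette_permutation_equivariance(self, d, perm):
        v = d[::-1].copy()
        mapping = {old: new for old, new in zip((1, 2, 3, 4, 5), perm)}
        remap = np.zeros(6, np.uint8)
        for old, new in mapping.items():
            remap[old] = new
        entries = tuple(
            (mapping[idx], name, col) for idx, name, col in DEFAULT_PALETTE.entries
        )
        permuted_palette = ClassPalette(
            tuple(sorted(entries)), background_index=mapping[1]
        )
        base = score_window(SymmetryWindow(d, v), DEFAULT_PALETTE)
        perm_res = score_window(
            SymmetryWindow(remap[d], remap[v]), permuted_palette
        )
        for old, new in mapping.items():
            assert base.scores[old] == perm_res.scores[new]
        assert base.combined == perm_res.combined


class TestRefineAngle:
    def test_symmetric_section_keeps_zero_offset(self, symmetric_section):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        ref = refine_angle(symmetric_section, axis, WindowSpec(), 5.0, 0.5)
        assert ref.rotation_deg == axis.rotation_deg

    def test_zero_search_returns_input_unchanged(self, symmetric_section):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        assert refine_angle(symmetric_section, axis, WindowSpec(), 0.0, 0.5) is axis

    def test_recovers_a_two_degree_tilt(self):
        spec = SectionSpec(
            height_px=384, width_px=384, seed=3, epidermis_thickness_px=10
        )
        lab = generate_label_section(spec)
        tilted = LabelImage(
            _rotate_raster(lab.labels, 2.0, order=0, cval=1), lab.palette, 4.0
        )
        axis = place_axis(tilted, *contour_axis_points(tilted))
        ref = refine_angle(tilted, axis, WindowSpec(), search_deg=5.0, step_deg=0.5)
        assert ref.rotation_deg - axis.rotation_deg == pytest.approx(-2.0)

    def test_no_epidermis_raises(self):
        lab = _blank(64, 64, fill=4)
        axis = place_axis(lab, (2, 32), (60, 32))
        with pytest.raises(ValueError, match="no epidermal contour"):
            refine_angle(lab, axis, WindowSpec(center_col=32, width_um=20), 2.0, 1.0)


class TestScoreSample:
    def test_twelve_windows_on_symmetric_section_all_one(self, symmetric_section):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        windows = [
            WindowSpec(center_col=c, width_um=80.0) for c in range(70, 190, 10)
        ]
        results = score_sample(
            symmetric_section, axis, windows, sample_id="s0"
        )
        assert len(results) == 12
        assert all(r.combined == 1.0 for r in results)
        assert {r.provenance["sample_id"] for r in results} == {"s0"}

    def test_consistent_with_single_window_calls(self):
        lab = generate_label_section(
            SectionSpec(height_px=256, width_px=256, asymmetry=1.0, seed=9)
        )
        axis = place_axis(lab, *contour_axis_points(lab))
        w1, w2 = WindowSpec(center_col=110), WindowSpec(center_col=140)
        batch = score_sample(lab, axis, [w1, w2])
        singles = [
            score_window(extract_window(lab, axis, w), lab.palette) for w in (w1, w2)
        ]
        assert [r.combined for r in batch] == [r.combined for r in singles]
        assert batch[0].combined != batch[1].combined

    def test_at_least_one_window_required(self, symmetric_section):
        axis = place_axis(symmetric_section, *contour_axis_points(symmetric_section))
        with pytest.raises(ValueError, match="at least one window"):
            score_sample(symmetric_section, axis, [])
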