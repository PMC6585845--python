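import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paveshape as ps
from paveshape import geometry
from conftest import circle_outline, ellipse_outline


class TestOutlineCanonicalization:
    def test_orientation_corrected_to_ccw(self):
        cw = ps.Outline([[0, 1], [1, 1], [1, 0], [0, 0]])
        assert geometry._signed_area(cw.vertices) > 0

    def test_consecutive_duplicates_dropped(self):
        o = ps.Outline([[0, 0], [0, 0], [1, 0], [1, 1], [0, 1], [0, 1], [0, 0]])
        assert len(o) == 4

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            ps.Outline([[0, 0], [1, 1]])

    def test_self_intersection_rejected(self):
        # pentagram: regular pentagon traversed in star order
        th = 2 * np.pi * np.arange(5) * 2 / 5 + np.pi / 2
        with pytest.raises(ValueError, match="self-intersect"):
            ps.Outline(np.column_stack([np.cos(th), np.sin(th)]))


class TestKernels:
    @pytest.mark.parametrize(
        "fixture, area, perim",
        [("unit_square", 1.0, 4.0), ("rect_2x1", 2.0, 6.0), ("plus_sign", 5.0, 12.0)],
    )
    def test_area_and_perimeter_exact(self, request, fixture, area, perim):
        o = request.getfixturevalue(fixture)
        assert ps.polygon_area(o) == pytest.approx(area)
        assert ps.perimeter(o) == pytest.approx(perim)

    def test_circle_perimeter(self):
        assert ps.perimeter(circle_outline(256)) == pytest.approx(2 * np.pi, rel=1e-3)

    def test_hull_of_convex_input_is_identity(self):
        tri = ps.Outline([[0, 0], [2, 0], [1, 2]])
        hull = ps.convex_hull(tri)
        assert sorted(map(tuple, hull.vertices)) == sorted(map(tuple, tri.vertices))

    def test_plus_sign_hull_is_octagon_of_area_7(self, plus_sign):
        hull = ps.convex_hull(plus_sign)
        assert len(hull) == 8
        assert ps.polygon_area(hull) == pytest.approx(7.0)

    def test_hull_idempotent_and_contains(self, plus_sign):
        h1 = ps.convex_hull(plus_sign)
        h2 = ps.convex_hull(h1)
        assert np.allclose(np.sort(h1.vertices, axis=0), np.sort(h2.vertices, axis=0))
        assert ps.polygon_area(h1) >= ps.polygon_area(plus_sign)


class TestResample:
    def test_unit_square_8_points_keeps_perimeter(self, unit_square):
        assert ps.perimeter(ps.resample(unit_square, 8)) == pytest.approx(4.0, rel=0.01)

    def test_circle_perimeter_preserved(self):
        r = ps.resample(circle_outline(1024), 256)
        assert ps.perimeter(r) == pytest.approx(2 * np.pi, rel=1e-3)

    def test_solidity_self_consistency_across_density(self):
        lob = ps.make_lobed_cell(ps.LobedCellParams(k=8, amp=0.25, n_points=2000))
        s500 = ps.solidity(ps.resample(lob, 500))
        s1000 = ps.solidity(ps.resample(lob, 1000))
        assert abs(s500 - s1000) < 1e-3

    def test_too_few_points_rejected(self, unit_square):
        with pytest.raises(ValueError, match=">= 8"):
            ps.resample(unit_square, 4)


class TestPrincipalExtents:
    def test_axis_aligned_rectangle(self, rect_2x1):
        ext = ps.principal_extents(ps.resample(rect_2x1, 300))
        assert (ext.length, ext.width) == pytest.approx((2.0, 1.0), rel=1e-9)

    def test_rotation_invariance(self, rect_2x1):
        base = ps.resample(rect_2x1, 300)
        rot = base.transformed(rotate=np.deg2rad(37.0), translate=(5.0, -2.0))
        ext = ps.principal_extents(rot)
        assert (ext.length, ext.width) == pytest.approx((2.0, 1.0), rel=1e-6)

    def test_ellipse_extents_match_axes(self):
        ext = ps.principal_extents(ellipse_outline(3.0, 1.0, n=2048))
        assert ext.length == pytest.approx(6.0, rel=5e-3)
        assert ext.width == pytest.approx(2.0, rel=5e-3)

    def test_isotropy_tie_flagged_with_zero_angle(self):
        ext = ps.principal_extents(circle_outline(360))
        assert ext.isotropic and ext.angle == 0.0

    def test_feret_option_uses_longest_chord(self, rect_2x1):
        ext = ps.principal_extents(ps.resample(rect_2x1, 300), method="feret")
        assert ext.length == pytest.approx(np.sqrt(5.0), rel=1e-6)  # the diagonal


class TestRigidMotionInvariance:
    @settings(max_examples=25, deadline=None)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        tx=st.floats(-50.0, 50.0),
        ty=st.floats(-50.0, 50.0),
        shift=st.integers(0, 299),
    )
    def test_descriptors_invariant_under_rigid_motion_and_cycle(self, angle, tx, ty, shift):
        base = ps.make_lobed_cell(ps.LobedCellParams(a=2.0, b=1.0, k=6, amp=0.2, n_points=300))
        moved = ps.Outline(np.roll(base.vertices, shift, axis=0)).transformed(
            rotate=angle, translate=(tx, ty)
        )
        assert ps.polygon_area(moved) == pytest.approx(ps.polygon_area(base), rel=1e-9)
        assert ps.perimeter(moved) == pytest.approx(ps.perimeter(base), rel=1e-9)
        assert ps.solidity(moved) == pytest.approx(ps.solidity(base), rel=1e-9)
        assert ps.circularity(moved) == pytest.approx(ps.circularity(base), rel=1e-9)
        assert ps.aspect_ratio(moved) == pytest.approx(ps.aspect_ratio(base), rel=1e-5)


class TestTraceOutlines:
    def test_square_block_has_exact_pixel_area(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 3:7] = 1
        (o,) = ps.trace_outlines(mask, min_area=0)
        assert ps.polygon_area(o) == pytest.approx(16.0)
        assert not o.border_touching

    def test_scale_applied(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 3:7] = 1
        (o,) = ps.trace_outlines(mask, ps.Scale(2.5), min_area=0)
        assert ps.polygon_area(o) == pytest.approx(16.0 * 2.5**2)

    def test_all_background_gives_empty_list(self):
        assert ps.trace_outlines(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_non_binary_mask_rejected_naming_values(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1, 1], mask[2, 2] = 1, 7
        with pytest.raises(ValueError, match=r"two pixel values.*\[0, 1, 7\]"):
            ps.trace_outlines(mask)

    def test_min_area_filters_speckle(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:4, 2:4] = 1        # 4 px speckle
        mask[10:25, 10:25] = 1    # 225 px cell
        outs = ps.trace_outlines(mask, min_area=50)
        assert len(outs) == 1
        assert ps.polygon_area(outs[0]) == pytest.approx(225.0)

    def test_border_touching_flagged(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[0:4, 2:6] = 1
        (o,) = ps.trace_outlines(mask, min_area=0)
        assert o.border_touching and "|border" in o.label

    def test_invert_flag_swaps_foreground(self):
        mask = np.ones((10, 10), dtype=np.uint8)
        mask[3:7, 3:7] = 0
        outs = ps.trace_outlines(mask, min_area=0, invert=True)
        inner = [o for o in outs if not o.border_touching]
        assert len(inner) == 1
        assert ps.polygon_area(inner[0]) == pytest.approx(16.0)


class TestRasterRoundTrip:
    @pytest.mark.parametrize("amp,ar", [(0.1, 0.8), (0.25, 0.5)])
    def test_metrics_recovered_at_200px_diameter(self, amp, ar):
        a = 110.0 / np.sqrt(ar)
        o = ps.make_lobed_cell(ps.LobedCellParams(a=a, b=a * ar, k=6, amp=amp, n_points=400))
        truth = ps.measure(o, n_points=400)
        mask = ps.rasterize(o, 1.0)
        (traced,) = ps.trace_outlines(mask, min_area=50)
        got = ps.measure(traced, n_points=400)
        assert abs(got.solidity - truth.solidity) < 0.02
        assert abs(got.aspect_ratio - truth.aspect_ratio) < 0.01

    def test_tolerance_tightens_with_resolution(self):
        errs = []
        for diam in (60.0, 240.0):
            o = ps.make_lobed_cell(ps.LobedCellParams(a=diam / 2, b=diam / 2, k=6, amp=0.2, n_points=400))
            truth = ps.measure(o, n_points=400)
            (traced,) = ps.trace_outlines(ps.rasterize(o, 1.0), min_area=10)
            errs.append(abs(ps.measure(traced, n_points=400).solidity - truth.solidity))
        assert errs[1] < errs[0]


class TestOutlineCSV:
    def test_frame_round_trip(self, plus_sign, unit_square):
        df = ps.outlines_to_frame([plus_sign, unit_square], species="sp1", side="adaxial")
        records = ps.frame_to_outlines(df)
        assert len(records) == 2
        for (species, _, side, o), src in zip(records, [plus_sign, unit_square]):
            assert species == "sp1" and side == "adaxial"
            assert ps.polygon_area(o) == pytest.approx(ps.polygon_area(src))

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            ps.frame_to_outlines(pd.DataFrame({"x_um": [0.0]}))
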