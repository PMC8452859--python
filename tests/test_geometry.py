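"""Polygon primitives, boolean ops, layouts, and the region-count law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point

import vennkit as vk
from vennkit.geometry import EPS_REL, GeometryError, PolyShape


def lens_area(r1, r2, d):
    """Closed-form intersection area of two circles (the oracle)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * math.sqrt((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    return a1 + a2 - tri


def convex_polygon(rng, n_pts=8):
    from scipy.spatial import ConvexHull

    pts = rng.random((n_pts, 2)) * 2 - 1
    h = ConvexHull(pts)
    return PolyShape.from_rings([pts[h.vertices]])


class TestPrimitives:
    def test_circle_area_converges(self):
        c = vk.circle((0, 0), 1.0, n_vertices=3600)
        assert c.area == pytest.approx(math.pi, abs=1e-4)

    def test_circle_four_vertices_is_square(self):
        c = vk.circle((0, 0), 2.0, n_vertices=4)
        assert c.area == pytest.approx(2 * 2.0 ** 2)

    def test_circle_centroid_is_center(self):
        c = vk.circle((0.3, -0.7), 0.5)
        assert c.geom.centroid.x == pytest.approx(0.3, abs=1e-9)
        assert c.geom.centroid.y == pytest.approx(-0.7, abs=1e-9)

    def test_circle_bad_radius(self):
        with pytest.raises(GeometryError):
            vk.circle((0, 0), 0.0)

    def test_ellipse_degenerates_to_circle(self):
        e = vk.ellipse((0, 0), (0.5, 0.5))
        c = vk.circle((0, 0), 0.5)
        assert e.geom.symmetric_difference(c.geom).area < 1e-12

    def test_ellipse_area(self):
        e = vk.ellipse((1, 2), (0.8, 0.3), rotation_deg=30, n_vertices=3600)
        assert e.area == pytest.approx(math.pi * 0.8 * 0.3, abs=1e-3)

    def test_ellipse_rotation_half_turn_same_shape(self):
        e0 = vk.ellipse((0, 0), (0.6, 0.2), rotation_deg=0)
        e180 = vk.ellipse((0, 0), (0.6, 0.2), rotation_deg=180)
        assert e0.geom.symmetric_difference(e180.geom).area < 1e-9

    def test_ellipse_bad_axes(self):
        with pytest.raises(GeometryError):
            vk.ellipse((0, 0), (1.0, -0.1))

    def test_triangle_area(self):
        t = vk.triangle([(0, 0), (1, 0), (0, 1)])
        assert t.area == pytest.approx(0.5)

    def test_triangle_collinear_rejected(self):
        with pytest.raises(GeometryError, match="collinear"):
            vk.triangle([(0, 0), (1, 1), (2, 2)])

    def test_rounded_rectangle_zero_radius_is_rectangle(self):
        r = vk.rounded_rectangle((0, 0), 2.0, 1.0, 0.0)
        assert r.area == pytest.approx(2.0)

    def test_rounded_rectangle_area_formula(self):
        w, h, rad = 2.0, 1.0, 0.25
        r = vk.rounded_rectangle((0, 0), w, h, rad, n_vertices=720)
        assert r.area == pytest.approx(w * h - (4 - math.pi) * rad ** 2, rel=1e-4)

    def test_rounded_rectangle_bad_params(self):
        with pytest.raises(GeometryError):
            vk.rounded_rectangle((0, 0), 1.0, 1.0, 0.6)


class TestBooleanOps:
    def test_unit_circle_lens_closed_form(self):
        a = vk.circle((0, 0), 1.0)
        b = vk.circle((1, 0), 1.0)
        expected = 2 * math.acos(0.5) - 0.5 * math.sqrt(3)
        got = vk.poly_intersect(a, b).area
        assert got == pytest.approx(expected, rel=1e-3)

    def test_disjoint_shapes(self):
        a = vk.circle((0, 0), 1.0)
        b = vk.circle((5, 0), 1.0)
        assert vk.poly_intersect(a, b).is_empty
        assert vk.poly_union(a, b).area == pytest.approx(a.area + b.area)

    def test_idempotence(self):
        a = vk.circle((0, 0), 1.0)
        assert vk.poly_difference(a, a).is_empty
        assert vk.poly_union(a, a).geom.symmetric_difference(a.geom).area < 1e-12

    def test_unclean_input_rejected(self):
        bowtie = PolyShape(
            __import__("shapely").geometry.Polygon([(0, 0), (1, 1), (1, 0), (0, 1)]))
        a = vk.circle((0, 0), 1.0)
        with pytest.raises(GeometryError, match="self-intersecting"):
            vk.poly_intersect(bowtie, a)

    def test_self_intersecting_ring_named_on_ingest(self):
        with pytest.raises(GeometryError, match="ring 0"):
            PolyShape.from_rings([np.array([(0, 0), (1, 1), (1, 0), (0, 1)])])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_boolean_algebra_on_random_convex_polygons(self, seed):
        rng = np.random.default_rng(seed)
        a, b = convex_polygon(rng), convex_polygon(rng)
        assert vk.poly_intersect(a, b).area == pytest.approx(
            vk.poly_intersect(b, a).area, abs=1e-12)
        assert vk.poly_union(a, b).area == pytest.approx(
            vk.poly_union(b, a).area, abs=1e-12)
        diff = vk.poly_difference(a, b)
        assert vk.poly_intersect(diff, b).area < 1e-12
        assert vk.poly_union(a, b).area == pytest.approx(
            a.area + b.area - vk.poly_intersect(a, b).area, abs=1e-9)

    @pytest.mark.parametrize("r1,r2,dfrac", [
        (1.0, 1.0, 0.3), (1.0, 1.0, 0.9), (1.5, 0.6, 0.5),
        (0.8, 0.8, 0.99), (2.0, 1.0, 0.4),
    ])
    def test_lens_area_grid(self, r1, r2, dfrac):
        d = dfrac * (r1 + r2)
        a = vk.circle((0, 0), r1, n_vertices=720)
        b = vk.circle((d, 0), r2, n_vertices=720)
        got = vk.poly_intersect(a, b).area
        assert got == pytest.approx(lens_area(r1, r2, d), rel=1e-3)


class TestLayouts:
    @pytest.mark.parametrize("n,family", [(2, "classic"), (3, "classic"), (4, "classic"),
                                          (3, "constructive"), (4, "constructive"),
                                          (5, "constructive"), (6, "constructive"),
                                          (7, "constructive")])
    def test_region_count_law(self, n, family):
        """Every built-in layout realizes all 2^n-1 regions, disjoint,
        with areas summing to the union area."""
        layout = vk.builtin_layout(n, family)
        report = vk.validate_layout(layout)
        assert report.valid, report.messages
        assert report.positive_regions == 2 ** n - 1

    @pytest.mark.parametrize("n", [0, 1, 8])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(vk.VennError, match="unsupported set count"):
            vk.builtin_layout(n)

    def test_classic_five_sets_directs_to_constructive(self):
        with pytest.raises(GeometryError, match="constructive"):
            vk.builtin_layout(5, "classic")

    def test_two_circle_layout_has_three_regions(self):
        regions = vk.compute_regions(vk.builtin_layout(2))
        assert sum(1 for r in regions if r.area > 0) == 3

    def test_layouts_deterministic(self):
        a = vk.builtin_layout(4, "classic")
        b = vk.builtin_layout(4, "classic")
        for sa_, sb in zip(a.shapes, b.shapes):
            assert sa_.geom.equals_exact(sb.geom, 0)
        e1, e2 = vk.edwards_layout(6), vk.edwards_layout(6)
        for sa_, sb in zip(e1.shapes, e2.shapes):
            assert sa_.geom.equals_exact(sb.geom, 0)

    def test_six_triangles_compose_valid_layout(self):
        layout = vk.six_triangle_layout()
        assert layout.n == 6
        for s in layout.shapes:  # each shape is a genuine triangle
            assert len(s.largest_part().exterior.coords) == 4
        report = vk.validate_layout(layout)
        assert report.valid and report.positive_regions == 63

    def test_four_rounded_rectangles_compose_valid_layout(self):
        layout = vk.rounded_rectangle_layout()
        report = vk.validate_layout(layout)
        assert report.valid and report.positive_regions == 15


class TestComputeRegions:
    def test_disjoint_circles(self):
        layout = vk.layout_from_shapes([vk.circle((0, 0), 1.0), vk.circle((5, 0), 1.0)])
        regions = {str(r.mask): r for r in vk.compute_regions(layout)}
        assert regions["11"].poly.is_empty
        assert regions["10"].area == pytest.approx(math.pi, rel=1e-4)
        assert regions["01"].area == pytest.approx(math.pi, rel=1e-4)

    def test_identical_circles(self):
        c = vk.circle((0, 0), 1.0)
        layout = vk.layout_from_shapes([c, c])
        regions = {str(r.mask): r for r in vk.compute_regions(layout)}
        assert regions["10"].poly.is_empty and regions["01"].poly.is_empty
        assert regions["11"].area == pytest.approx(c.area)

    @pytest.mark.parametrize("n,family", [(3, "classic"), (4, "classic"), (6, "constructive")])
    def test_region_areas_sum_to_union(self, n, family):
        from shapely.ops import unary_union
        layout = vk.builtin_layout(n, family)
        regions = vk.compute_regions(layout)
        union = unary_union([s.geom for s in layout.shapes]).area
        assert sum(r.area for r in regions) == pytest.approx(union, rel=EPS_REL * 10)

    def test_invalid_pseudolayout_reported(self):
        layout = vk.layout_from_shapes([vk.circle((0, 0), 1.0), vk.circle((5, 0), 1.0)])
        report = vk.validate_layout(layout)
        assert not report.valid
        assert report.positive_regions == 2


class TestLabelAnchors:
    def test_circle_anchor_near_center(self):
        a = vk.region_label_anchor(vk.circle((0.4, 0.6), 0.25))
        assert math.hypot(a.x - 0.4, a.y - 0.6) < 0.01

    def test_crescent_anchor_inside_even_when_centroid_is_not(self):
        big = vk.circle((0, 0), 1.0)
        bite = vk.circle((0.06, 0), 0.97)
        crescent = vk.poly_difference(big, bite)
        centroid = crescent.geom.centroid
        anchor = vk.region_label_anchor(crescent)
        assert crescent.geom.contains(Point(anchor.x, anchor.y))
        # the centroid of a thin crescent falls outside the region
        assert not crescent.geom.contains(centroid)

    def test_multipart_anchor_in_largest_part(self):
        from shapely.geometry import MultiPolygon
        small = vk.circle((0, 0), 0.2).geom
        large = vk.circle((3, 0), 1.0).geom
        multi = PolyShape(MultiPolygon([small, large]))
        anchor = vk.region_label_anchor(multi)
        assert large.contains(Point(anchor.x, anchor.y))

    def test_empty_region_has_no_anchor(self):
        from shapely.geometry import Polygon
        assert vk.region_label_anchor(PolyShape(Polygon())) is None

    def test_set_label_anchors_outside_symmetric_circles(self):
        layout = vk.builtin_layout(2)
        for i in range(2):
            a = vk.label_position(layout, i)
            p = Point(a.x, a.y)
            assert not any(s.geom.contains(p) for s in layout.shapes)

    def test_label_position_override_and_errors(self):
        layout = vk.builtin_layout(2)
        override = vk.AnchorPoint(9.0, 9.0)
        assert vk.label_position(layout, 0, override=override) == override
        with pytest.raises(GeometryError):
            vk.label_position(layout, 5)

    def test_label_positions_deterministic(self):
        layout = vk.builtin_layout(3)
        a = [vk.label_position(layout, i) for i in range(3)]
        b = [vk.label_position(layout, i) for i in range(3)]
        assert a == b


class TestShapesCsv:
    def test_roundtrip(self, tmp_path):
        shapes = [vk.circle((0, 0), 1.0, n_vertices=64), vk.triangle([(0, 0), (2, 0), (0, 2)])]
        path = tmp_path / "shapes.csv"
        vk.write_shapes_csv(shapes, path)
        back = vk.load_shapes_csv(path)
        assert len(back) == 2
        for orig, rt in zip(shapes, back):
            assert orig.geom.symmetric_difference(rt.geom).area < 1e-12

    def test_custom_layout_from_csv(self, tmp_path):
        shapes = [vk.circle((0.4, 0.5), 0.3, n_vertices=128),
                  vk.circle((0.6, 0.5), 0.3, n_vertices=128)]
        path = tmp_path / "two.csv"
        vk.write_shapes_csv(shapes, path)
        layout = vk.custom_layout(path)
        assert layout.provenance == "custom"
        assert vk.validate_layout(layout).valid

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(GeometryError, match="columns"):
            vk.load_shapes_csv(path)
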