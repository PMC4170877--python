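import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from oracles import fan_triangulation_centroid, mc_polygon_area, random_convex_polygon
from pcaboot import (
    ConfidencePolygon,
    convex_hull,
    polygon_area,
    polygon_centroid,
    polygons_overlap,
    signed_polygon_area,
    trim_cloud,
)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _poly(vertices, oid="x", alpha=0.0):
    return ConfidencePolygon(
        object_id=oid,
        vertices=np.asarray(vertices, dtype=float),
        area=polygon_area(vertices),
        centroid=polygon_centroid(vertices),
        alpha=alpha,
        n_points_in=len(vertices),
    )


class TestConvexHull:
    def test_interior_point_excluded(self):
        pts = np.vstack([UNIT_SQUARE, [[0.5, 0.5]]])
        verts, degen = convex_hull(pts)
        assert not degen
        assert {tuple(v) for v in verts} == {tuple(v) for v in UNIT_SQUARE}

    def test_triangle_is_its_own_hull(self):
        tri = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 2.0]])
        verts, degen = convex_hull(tri)
        assert not degen and len(verts) == 3

    def test_all_points_inside_or_on(self, rng):
        pts = rng.normal(size=(200, 2))
        verts, _ = convex_hull(pts)
        # independent containment oracle: shapely with a tolerance buffer
        hull = Polygon(verts).buffer(1e-9)
        assert all(hull.covers(Point(x, y)) for x, y in pts)
        # and the package's own half-plane test agrees
        assert _poly(verts).contains(pts).all()

    def test_collinear_cloud_degenerate(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        verts, degen = convex_hull(pts)
        assert degen and len(verts) == 2
        np.testing.assert_allclose(verts, [[0, 0], [4, 8]])

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            convex_hull(np.empty((0, 2)))


class TestTrimCloud:
    def test_alpha_zero_identity(self, rng):
        pts = rng.normal(size=(50, 2))
        np.testing.assert_array_equal(trim_cloud(pts, 0.0), pts)

    def test_retention_count_contract(self, rng):
        pts = rng.normal(size=(100, 2))
        kept = trim_cloud(pts, 0.10)
        assert kept.shape[0] >= 90

    @pytest.mark.parametrize("method", ["peel", "mahalanobis"])
    def test_outlier_trimming_shrinks_hull(self, method, rng):
        cluster = rng.normal(size=(95, 2))
        outliers = rng.normal(size=(5, 2)) * 0.2 + 20.0
        pts = np.vstack([cluster, outliers])
        a0 = polygon_area(convex_hull(pts)[0])
        a10 = polygon_area(convex_hull(trim_cloud(pts, 0.10, method=method))[0])
        assert a10 < a0

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            trim_cloud(np.zeros((5, 2)), 1.0)


class TestShoelace:
    def test_unit_square(self):
        assert polygon_area(UNIT_SQUARE) == pytest.approx(1.0)

    def test_right_triangle(self):
        tri = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        assert polygon_area(tri) == pytest.approx(6.0)

    def test_winding_and_rotation_invariance(self, rng):
        poly = random_convex_polygon(rng)
        a = polygon_area(poly)
        assert polygon_area(poly[::-1]) == pytest.approx(a)
        assert polygon_area(np.roll(poly, 3, axis=0)) == pytest.approx(a)
        assert signed_polygon_area(poly[::-1]) == pytest.approx(
            -signed_polygon_area(poly)
        )

    def test_monte_carlo_oracle(self, rng):
        poly = random_convex_polygon(rng, n_points=40)
        area = polygon_area(poly)
        mc, se = mc_polygon_area(poly, 10**6, rng)
        assert abs(area - mc) <= 3 * se

    def test_shapely_cross_check(self, rng):
        poly = random_convex_polygon(rng)
        assert polygon_area(poly) == pytest.approx(Polygon(poly).area, rel=1e-12)

    def test_degenerate_vertex_count(self):
        with pytest.raises(ValueError):
            polygon_area(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestCentroid:
    def test_unit_square(self):
        assert polygon_centroid(UNIT_SQUARE) == pytest.approx((0.5, 0.5))

    def test_triangle_centroid_is_vertex_mean(self, rng):
        tri = rng.normal(size=(3, 2))
        np.testing.assert_allclose(
            polygon_centroid(tri), tri.mean(axis=0), atol=1e-12
        )

    def test_fan_triangulation_oracle(self, rng):
        for _ in range(20):
            poly = random_convex_polygon(rng)
            np.testing.assert_allclose(
                polygon_centroid(poly),
                fan_triangulation_centroid(poly),
                atol=1e-9,
            )

    def test_centroid_strictly_inside_convex_polygon(self, rng):
        poly = random_convex_polygon(rng)
        assert _poly(poly).contains(np.array([polygon_centroid(poly)]))[0]

    def test_zero_area_fallback_to_vertex_mean(self):
        flat = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        np.testing.assert_allclose(polygon_centroid(flat), [1.0, 0.0])


class TestInvariances:
    @settings(derandomize=True, max_examples=25)
    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        theta=st.floats(0, 6.283),
        scale=st.floats(0.01, 100),
    )
    def test_rigid_motion_and_scaling(self, dx, dy, theta, scale):
        poly = random_convex_polygon(np.random.default_rng(99))
        a0 = polygon_area(poly)
        c0 = np.array(polygon_centroid(poly))
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = poly @ rot.T + [dx, dy]
        assert polygon_area(moved) == pytest.approx(a0, rel=1e-9)
        np.testing.assert_allclose(
            polygon_centroid(moved), rot @ c0 + [dx, dy], atol=1e-6 * max(1, scale)
        )
        scaled = poly * scale
        assert polygon_area(scaled) == pytest.approx(a0 * scale**2, rel=1e-9)
        np.testing.assert_allclose(polygon_centroid(scaled), c0 * scale, rtol=1e-9)


class TestOverlap:
    def test_self_overlap(self):
        pg = _poly(UNIT_SQUARE)
        flag, area = polygons_overlap(pg, pg)
        assert flag and area == pytest.approx(pg.area)

    def test_disjoint(self):
        a = _poly(UNIT_SQUARE)
        b = _poly(UNIT_SQUARE + 10.0)
        flag, area = polygons_overlap(a, b)
        assert not flag and area == 0.0

    def test_half_offset_squares(self):
        a = _poly(UNIT_SQUARE)
        b = _poly(UNIT_SQUARE + 0.5)
        flag, area = polygons_overlap(a, b)
        assert flag and area == pytest.approx(0.25)

    def test_symmetry(self, rng):
        a = _poly(random_convex_polygon(rng))
        b = _poly(random_convex_polygon(rng))
        fa, aa = polygons_overlap(a, b)
        fb, ab = polygons_overlap(b, a)
        assert fa == fb and aa == pytest.approx(ab)
        assert aa <= min(a.area, b.area) + 1e-12
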