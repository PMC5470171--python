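"""Geometry: shoelace area, monotone-chain hull vs brute-force oracle,
convexity invariances, stomatal index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafpheno.morphometrics import (
    CellPolygon,
    EpidermisCounts,
    convex_hull,
    convexity,
    convexity_vs_area,
    polygon_area,
    stomatal_index,
)
from leafpheno.synthetic import simulate_polygons

from conftest import brute_force_hull, canonical_cycle, random_simple_polygon, shoelace_area

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
L_SHAPE = np.array(
    [[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float
)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(CellPolygon("sq", UNIT_SQUARE)) == 1.0

    def test_orientation_invariance(self):
        assert polygon_area(CellPolygon("sq", UNIT_SQUARE[::-1])) == 1.0

    def test_l_shape(self):
        assert polygon_area(CellPolygon("L", L_SHAPE)) == 3.0


class TestConvexHull:
    def test_convex_input_unchanged(self):
        hull = convex_hull(CellPolygon("sq", UNIT_SQUARE))
        assert np.array_equal(
            canonical_cycle(hull.vertices), canonical_cycle(UNIT_SQUARE)
        )

    def test_l_shape_hull(self):
        hull = convex_hull(CellPolygon("L", L_SHAPE))
        expected = np.array([[0, 0], [2, 0], [2, 1], [1, 2], [0, 2]], dtype=float)
        assert np.array_equal(
            canonical_cycle(hull.vertices), canonical_cycle(expected)
        )
        assert polygon_area(hull) == 3.5

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            poly = random_simple_polygon(rng)
            hull = canonical_cycle(convex_hull(poly).vertices)
            oracle = brute_force_hull(poly.vertices)
            assert np.array_equal(hull, oracle)
            assert shoelace_area(hull) == shoelace_area(oracle)

    def test_idempotent(self, rng):
        for _ in range(20):
            poly = random_simple_polygon(rng)
            h1 = convex_hull(poly)
            h2 = convex_hull(h1)
            assert np.array_equal(
                canonical_cycle(h1.vertices), canonical_cycle(h2.vertices)
            )

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(ValueError):
            # degenerate: zero area already rejected at polygon construction
            CellPolygon("line", line)


class TestConvexity:
    def test_convex_polygons_have_convexity_one(self, rng):
        for _ in range(20):
            poly = random_simple_polygon(rng)
            hull = convex_hull(poly)
            assert convexity(hull) == pytest.approx(1.0, abs=1e-12)

    def test_l_shape_value(self):
        assert convexity(CellPolygon("L", L_SHAPE)) == pytest.approx(6 / 7)

    def test_deeper_notch_lower_convexity(self):
        # square with a notch of increasing depth at fixed hull
        def notched(depth):
            v = np.array(
                [[0, 0], [2, 0], [2, 2], [1.2, 2], [1.0, 2 - depth], [0.8, 2], [0, 2]],
                dtype=float,
            )
            return CellPolygon("n", v)

        values = [convexity(notched(d)) for d in (0.2, 0.6, 1.2)]
        assert values[0] > values[1] > values[2]

    @given(
        scale=st.floats(0.01, 100),
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        seed=st.integers(0, 500),
    )
    @settings(max_examples=40, deadline=None)
    def test_similarity_invariance(self, scale, angle, dx, dy, seed):
        poly = random_simple_polygon(np.random.default_rng(seed))
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        verts = scale * poly.vertices @ rot.T + np.array([dx, dy])
        transformed = CellPolygon("t", verts)
        assert convexity(transformed) == pytest.approx(convexity(poly), rel=1e-8)

    def test_bounds_on_random_polygons(self, rng):
        for _ in range(50):
            v = convexity(random_simple_polygon(rng))
            assert 0 < v <= 1


class TestConvexityVsArea:
    def test_all_convex_curve_is_one(self):
        polys = simulate_polygons(30, lobe_amplitude=0.0, lobe_count=6, seed=3)
        per_cell, curve = convexity_vs_area([(p, "g") for p in polys])
        assert np.allclose(curve["mean_convexity"], 1.0, atol=1e-6)

    def test_scale_invariance_across_genotypes(self):
        # same lobe parameters at different size scales: per-cell convexity
        # distributions agree
        small = simulate_polygons(150, 0.3, 8, seed=5, mean_radius_um=10)
        large = simulate_polygons(150, 0.3, 8, seed=6, mean_radius_um=40)
        cells = [(p, "small") for p in small] + [(p, "large") for p in large]
        per_cell, _ = convexity_vs_area(cells)
        med = per_cell.groupby("genotype")["convexity"].median()
        assert med["small"] == pytest.approx(med["large"], abs=0.02)

    def test_rescaling_leaves_convexity_unchanged(self):
        polys = simulate_polygons(10, 0.35, 8, seed=7)
        doubled = [CellPolygon(p.cell_id, p.vertices * 2.0) for p in polys]
        for p, q in zip(polys, doubled):
            assert convexity(q) == pytest.approx(convexity(p), rel=1e-12)


class TestStomatalIndex:
    @pytest.mark.parametrize(
        "guard, total, expected", [(0, 100, 0.0), (100, 100, 100.0), (20, 100, 20.0)]
    )
    def test_values(self, guard, total, expected):
        assert stomatal_index(EpidermisCounts(guard, total)) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            stomatal_index(EpidermisCounts(0, 0))

    def test_guard_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            EpidermisCounts(5, 3)


def test_geometry_agrees_with_shapely(rng):
    """Independent cross-check: shoelace areas and hull areas match
    shapely's polygon engine on random simple polygons."""
    shapely = pytest.importorskip("shapely")
    for _ in range(30):
        poly = random_simple_polygon(rng)
        sp = shapely.Polygon(poly.vertices)
        assert polygon_area(poly) == pytest.approx(sp.area, rel=1e-12)
        hull_area = polygon_area(convex_hull(poly))
        assert hull_area == pytest.approx(sp.convex_hull.area, rel=1e-12)
        assert convexity(poly) == pytest.approx(sp.area / sp.convex_hull.area,
                                                rel=1e-12)


def test_self_intersecting_polygon_rejected():
    bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
    with pytest.raises(ValueError, match="self-intersecting"):
        CellPolygon("bow", bowtie)
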