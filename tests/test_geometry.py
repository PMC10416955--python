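import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point as ShpPoint
from shapely.geometry import Polygon as ShpPolygon

from feedtrack.geometry import (
    BBox,
    Circle,
    Point,
    Polygon,
    centroid,
    euclidean_distance,
    point_in_circle,
    point_in_polygon,
    rect_circle_intersection_area,
)

# ---------------------------------------------------------------------------
# oracles


def mc_intersection_area(b: BBox, c: Circle, n: int, seed: int):
    """Monte-Carlo estimate of |b ∩ c| by uniform sampling over the box.

    Returns (estimate, standard_error).
    """
    rng = np.random.default_rng(seed)
    xs = rng.uniform(b.x, b.x + b.w, n)
    ys = rng.uniform(b.y, b.y + b.h, n)
    inside = (xs - c.cx) ** 2 + (ys - c.cy) ** 2 <= c.r**2
    p = inside.mean()
    se = math.sqrt(p * (1.0 - p) / n) * b.area
    return p * b.area, se


def winding_number_contains(px: float, py: float, verts) -> bool:
    """Independent winding-number membership (nonzero rule)."""

    def is_left(x1, y1, x2, y2):
        return (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)

    wn = 0
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 <= py:
            if y2 > py and is_left(x1, y1, x2, y2) > 0:
                wn += 1
        elif y2 <= py and is_left(x1, y1, x2, y2) < 0:
            wn -= 1
    return wn != 0


def random_star_polygon(rng, n_vertices: int):
    """A random simple (possibly concave) star-shaped polygon around (0, 0)."""
    while True:
        angles = np.sort(rng.uniform(0.0, 2.0 * math.pi, n_vertices))
        radii = rng.uniform(1.0, 10.0, n_vertices)
        verts = [(r * math.cos(a), r * math.sin(a)) for r, a in zip(radii, angles)]
        if ShpPolygon(verts).is_valid:
            return verts


# ---------------------------------------------------------------------------
# construction and trivial operations


class TestTypes:
    def test_bbox_rejects_nonpositive_extent(self):
        with pytest.raises(ValueError):
            BBox(0, 0, 0, 1)
        with pytest.raises(ValueError):
            BBox(0, 0, 1, -2)

    def test_bbox_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            BBox(math.nan, 0, 1, 1)

    def test_circle_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            Circle(0, 0, 0)

    def test_polygon_rejects_too_few_vertices(self):
        with pytest.raises(ValueError):
            Polygon([(0, 0), (1, 1)])

    def test_polygon_rejects_self_intersection(self):
        with pytest.raises(ValueError):
            Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # bow-tie

    def test_polygon_rejects_zero_area(self):
        with pytest.raises(ValueError):
            Polygon([(0, 0), (1, 1), (2, 2)])


@pytest.mark.parametrize(
    "box,expected",
    [
        (BBox(10, 20, 4, 6), Point(12, 23)),
        (BBox(0, 0, 2, 2), Point(1, 1)),
        (BBox(5.5, 5.5, 1, 1), Point(6, 6)),
    ],
)
def test_centroid(box, expected):
    assert centroid(box) == expected


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (Point(0, 0), Point(3, 4), 5.0),
        (Point(7, 7), Point(7, 7), 0.0),
        (Point(0, 0), Point(1, 1), math.sqrt(2.0)),
    ],
)
def test_euclidean_distance(a, b, expected):
    assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)


@given(st.tuples(*[st.floats(-1e6, 1e6) for _ in range(4)]))
def test_distance_symmetric_nonnegative(coords):
    a, b = Point(coords[0], coords[1]), Point(coords[2], coords[3])
    assert euclidean_distance(a, b) == euclidean_distance(b, a) >= 0.0


# ---------------------------------------------------------------------------
# membership


def test_point_in_circle_cases():
    c = Circle(0, 0, 1)
    assert point_in_circle(Point(0, 0), c)
    assert point_in_circle(Point(0, 1), c)  # boundary counts as inside
    assert not point_in_circle(Point(0, 1.0001), c)


def test_point_in_polygon_cases(unit_square):
    assert point_in_polygon(Point(1, 1), unit_square)
    assert not point_in_polygon(Point(3, 3), unit_square)
    assert point_in_polygon(Point(0, 1), unit_square)  # boundary


def test_point_in_polygon_matches_winding_oracle():
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(60):
        verts = random_star_polygon(rng, int(rng.integers(3, 9)))
        poly = Polygon(verts)
        shp = ShpPolygon(verts)
        for _ in range(40):
            px, py = rng.uniform(-12.0, 12.0, 2)
            if shp.exterior.distance(ShpPoint(px, py)) < 1e-6:
                continue  # boundary ties are convention-dependent
            assert point_in_polygon(Point(px, py), poly) == winding_number_contains(px, py, verts)
            checked += 1
    assert checked > 1000


# ---------------------------------------------------------------------------
# rectangle-circle intersection area


class TestRectCircleArea:
    def test_box_inside_circle(self):
        assert rect_circle_intersection_area(BBox(-1, -1, 2, 2), Circle(0, 0, 10)) == pytest.approx(4.0, rel=1e-12)

    def test_disjoint(self):
        assert rect_circle_intersection_area(BBox(100, 100, 5, 5), Circle(0, 0, 10)) == 0.0

    def test_disjoint_diagonal_with_overlapping_bounds(self):
        # bounding boxes overlap, shapes do not; must be exactly zero
        assert rect_circle_intersection_area(BBox(45, 45, 28, 28), Circle(0, 0, 60)) == 0.0

    def test_circle_inside_box(self):
        assert rect_circle_intersection_area(BBox(-20, -20, 40, 40), Circle(0, 0, 3)) == pytest.approx(
            9 * math.pi, rel=1e-12
        )

    def test_half_plane(self):
        assert rect_circle_intersection_area(BBox(0, -10, 20, 20), Circle(0, 0, 4)) == pytest.approx(
            8 * math.pi, rel=1e-12
        )

    def test_quarter_plane(self):
        assert rect_circle_intersection_area(BBox(0, 0, 50, 50), Circle(0, 0, 4)) == pytest.approx(
            4 * math.pi, rel=1e-12
        )

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        for i in range(25):
            r = rng.uniform(1.0, 5.0)
            c = Circle(rng.uniform(-3, 3), rng.uniform(-3, 3), r)
            b = BBox(c.cx - rng.uniform(0.2, 1.5) * r, c.cy - rng.uniform(0.2, 1.5) * r,
                     rng.uniform(0.5, 3.0) * r, rng.uniform(0.5, 3.0) * r)
            exact = rect_circle_intersection_area(b, c)
            est, se = mc_intersection_area(b, c, n=200_000, seed=1000 + i)
            assert abs(exact - est) <= 3.0 * se + 1e-9

    @given(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0.5, 20), st.floats(0.5, 20),
        st.floats(-50, 50), st.floats(-50, 50), st.floats(0.5, 20),
        st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
    )
    @settings(max_examples=200)
    def test_translation_invariance_and_bounds(self, bx, by, w, h, cx, cy, r, tx, ty):
        b, c = BBox(bx, by, w, h), Circle(cx, cy, r)
        area = rect_circle_intersection_area(b, c)
        assert 0.0 <= area <= min(b.area, c.area) + 1e-9
        shifted = rect_circle_intersection_area(BBox(bx + tx, by + ty, w, h), Circle(cx + tx, cy + ty, r))
        assert shifted == pytest.approx(area, rel=1e-9, abs=1e-9)

    @given(
        st.floats(-10, 10), st.floats(-10, 10),
        st.floats(0.5, 10), st.floats(0.5, 10),
        st.floats(0.1, 5), st.floats(0.1, 5),
    )
    @settings(max_examples=200)
    def test_monotone_in_box_growth(self, bx, by, w, h, r, grow):
        c = Circle(0.0, 0.0, r)
        small = rect_circle_intersection_area(BBox(bx, by, w, h), c)
        big = rect_circle_intersection_area(BBox(bx - grow, by - grow, w + 2 * grow, h + 2 * grow), c)
        assert big >= small - 1e-9

    def test_monotone_in_radius(self):
        b = BBox(2.0, -1.0, 4.0, 3.0)
        areas = [rect_circle_intersection_area(b, Circle(0, 0, r)) for r in np.linspace(0.5, 10, 40)]
        assert all(a2 >= a1 - 1e-9 for a1, a2 in zip(areas, areas[1:]))
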