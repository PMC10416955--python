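"""Continuous 2-D geometry for axis-aligned boxes, circles, and polygons.

Coordinates are continuous pixel units in image convention: origin at the
top-left corner, y increasing downward.  Boxes are (left, top, width,
height).  Boundary points count as *inside* for both circle and polygon
membership tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

from shapely.geometry import Point as _ShpPoint
from shapely.geometry import Polygon as _ShpPolygon

__all__ = [
    "Point",
    "BBox",
    "Circle",
    "Polygon",
    "centroid",
    "euclidean_distance",
    "rect_circle_intersection_area",
    "point_in_circle",
    "point_in_polygon",
]

_ABS_TOL = 1e-9


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: coordinates must be finite, got {v!r}")


@dataclass(frozen=True)
class Point:
    """A point in continuous pixel coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        _require_finite("Point", self.x, self.y)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box: (left, top, width, height)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        _require_finite("BBox", self.x, self.y, self.w, self.h)
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"BBox extents must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> Point:
        return Point(self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass(frozen=True)
class Circle:
    """A circle given by its center and radius."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        _require_finite("Circle", self.cx, self.cy, self.r)
        if self.r <= 0:
            raise ValueError(f"Circle radius must be positive, got {self.r}")

    @property
    def area(self) -> float:
        return math.pi * self.r * self.r

    @property
    def center(self) -> Point:
        return Point(self.cx, self.cy)


PointLike = Union[Point, Tuple[float, float], Sequence[float]]


def _as_xy(p: PointLike) -> Tuple[float, float]:
    if isinstance(p, Point):
        return (p.x, p.y)
    x, y = p  # type: ignore[misc]
    return (float(x), float(y))


class Polygon:
    """A simple (non-self-intersecting) polygon with positive enclosed area.

    Vertices may be given as :class:`Point` instances or ``(x, y)`` pairs.
    Degenerate polygons (fewer than three vertices, self-intersecting rings,
    or zero area) are rejected at construction.
    """

    __slots__ = ("vertices", "_shape")

    def __init__(self, vertices: Iterable[PointLike]):
        pts = tuple(Point(*_as_xy(v)) for v in vertices)
        if len(pts) < 3:
            raise ValueError("Polygon needs at least 3 vertices")
        shape = _ShpPolygon([(p.x, p.y) for p in pts])
        if not shape.is_valid:
            raise ValueError("Polygon must be simple (non-self-intersecting)")
        if shape.area <= 0:
            raise ValueError("Polygon must enclose positive area")
        self.vertices = pts
        self._shape = shape

    @property
    def area(self) -> float:
        return self._shape.area

    def bounds(self) -> Tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the vertex ring."""
        return self._shape.bounds

    def covers_point(self, p: Point) -> bool:
        return bool(self._shape.covers(_ShpPoint(p.x, p.y)))

    def contains_circle(self, c: Circle) -> bool:
        """True iff the full disk lies inside the polygon (boundary contact allowed)."""
        center = _ShpPoint(c.cx, c.cy)
        if not self._shape.covers(center):
            return False
        return self._shape.exterior.distance(center) >= c.r - _ABS_TOL

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Polygon({len(self.vertices)} vertices, area={self.area:.1f})"


def centroid(b: BBox) -> Point:
    """Central point of a bounding box."""
    return b.center


def euclidean_distance(a: Point, b: Point) -> float:
    return math.hypot(a.x - b.x, a.y - b.y)


def point_in_circle(p: Point, c: Circle) -> bool:
    """True iff ``p`` lies inside or on the boundary of ``c``."""
    return euclidean_distance(p, c.center) <= c.r


def point_in_polygon(p: Point, poly: Polygon) -> bool:
    """Even-odd membership; boundary counts as inside."""
    return poly.covers_point(p)


def _disk_polygon_area(cx: float, cy: float, r: float,
                       ring: Sequence[Tuple[float, float]]) -> float:
    """Exact area of disk((cx,cy), r) ∩ simple polygon ``ring``.

    Green's-theorem decomposition: each directed edge, translated so the
    circle is at the origin, is split at its circle crossings; sub-segments
    inside the disk contribute a signed triangle area, sub-segments outside
    contribute the signed circular sector they subtend.  Requires the ring
    to wind with positive shoelace area.
    """
    total = 0.0
    n = len(ring)
    r2 = r * r
    for i in range(n):
        ax = ring[i][0] - cx
        ay = ring[i][1] - cy
        bx = ring[(i + 1) % n][0] - cx
        by = ring[(i + 1) % n][1] - cy
        dx = bx - ax
        dy = by - ay
        seg2 = dx * dx + dy * dy
        if seg2 == 0.0:
            continue
        # |a + t d|^2 = r^2  ->  seg2 t^2 + 2(a.d) t + (|a|^2 - r^2) = 0
        bq = ax * dx + ay * dy
        cq = ax * ax + ay * ay - r2
        ts = [0.0, 1.0]
        disc = bq * bq - seg2 * cq
        if disc > 0.0:
            sq = math.sqrt(disc)
            for t in ((-bq - sq) / seg2, (-bq + sq) / seg2):
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts.sort()
        for t0, t1 in zip(ts, ts[1:]):
            if t1 - t0 <= 0.0:
                continue
            tm = 0.5 * (t0 + t1)
            mx = ax + tm * dx
            my = ay + tm * dy
            px = ax + t0 * dx
            py = ay + t0 * dy
            qx = ax + t1 * dx
            qy = ay + t1 * dy
            if mx * mx + my * my <= r2:
                total += 0.5 * (px * qy - py * qx)
            else:
                # angle subtended at the center; always < pi for a straight
                # sub-segment fully outside the disk
                total += 0.5 * r2 * math.atan2(px * qy - py * qx,
                                               px * qx + py * qy)
    return total


def rect_circle_intersection_area(b: BBox, c: Circle) -> float:
    """Exact area of ``b ∩ c`` in square pixels (closed form, no sampling)."""
    # quick rejection: box and circle bounding boxes disjoint
    if (b.x > c.cx + c.r or b.x + b.w < c.cx - c.r
            or b.y > c.cy + c.r or b.y + b.h < c.cy - c.r):
        return 0.0
    # positive-shoelace winding of the rectangle ring
    ring = (
        (b.x, b.y),
        (b.x + b.w, b.y),
        (b.x + b.w, b.y + b.h),
        (b.x, b.y + b.h),
    )
    area = _disk_polygon_area(c.cx, c.cy, c.r, ring)
    if area < _ABS_TOL:  # snap float residue of (near-)disjoint configs to 0
        return 0.0
    return min(area, b.area, c.area)
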