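"""Planar geometry primitives for sagittal pelvic anatomy.

Coordinate convention: all coordinates are in millimetres in the sagittal
plane through the treatment isocenter.  ``a`` is the anterior-posterior
coordinate (anterior positive), ``s`` the superior-inferior coordinate
(superior positive), origin at the isocenter.  This matches the clinical
sign convention where positive shifts point left / superior / anterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon


class GeometryError(ValueError):
    """Raised for degenerate contours or unmeasurable constructions."""


@dataclass(frozen=True)
class Point2D:
    """A point in the sagittal plane (mm, anterior-positive a, superior-positive s)."""

    a: float
    s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.s)):
            raise GeometryError(f"non-finite point ({self.a}, {self.s})")

    def translated(self, da: float, ds: float) -> "Point2D":
        return Point2D(self.a + da, self.s + ds)

    def as_tuple(self) -> tuple[float, float]:
        return (self.a, self.s)


class Contour:
    """A simple closed polygon given by ordered vertices.

    Invariants: at least 3 vertices, non-self-intersecting, positive area.
    Vertices are stored as an (n, 2) float array of (a, s) pairs; the
    closing edge from the last vertex back to the first is implicit.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Iterable[Sequence[float]] | np.ndarray):
        arr = np.asarray(list(vertices) if not isinstance(vertices, np.ndarray) else vertices,
                         dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise GeometryError("contour vertices must be an (n, 2) sequence")
        if arr.shape[0] < 3:
            raise GeometryError("contour needs at least 3 vertices")
        if not np.all(np.isfinite(arr)):
            raise GeometryError("contour has non-finite vertices")
        poly = Polygon(arr)
        if not poly.is_valid:
            raise GeometryError("contour is self-intersecting or degenerate")
        if poly.area <= 0:
            raise GeometryError("contour encloses no area")
        self.vertices = arr

    # -- derived geometry -------------------------------------------------
    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def centroid(self) -> Point2D:
        c = self.polygon.centroid
        return Point2D(c.x, c.y)

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_a, min_s, max_a, max_s) of the vertex set."""
        mn = self.vertices.min(axis=0)
        mx = self.vertices.max(axis=0)
        return (mn[0], mn[1], mx[0], mx[1])

    def translated(self, da: float, ds: float) -> "Contour":
        return Contour(self.vertices + np.array([da, ds]))

    def contains(self, other: "Contour") -> bool:
        return self.polygon.contains(other.polygon)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Contour) and np.array_equal(self.vertices, other.vertices)

    def __repr__(self) -> str:
        return f"Contour({len(self.vertices)} vertices, area={self.area:.1f} mm^2)"


def horizontal_line_crossings(contour: Contour, s_level: float) -> np.ndarray:
    """Sorted ``a`` coordinates where the AP-parallel line s = s_level crosses the boundary."""
    return _line_crossings(contour, axis=1, level=s_level)


def vertical_line_crossings(contour: Contour, a_level: float) -> np.ndarray:
    """Sorted ``s`` coordinates where the SI-parallel line a = a_level crosses the boundary."""
    return _line_crossings(contour, axis=0, level=a_level)


def _line_crossings(contour: Contour, axis: int, level: float) -> np.ndarray:
    """Crossings of an axis-parallel line with the polygon boundary.

    ``axis`` is the coordinate held fixed by the line (0 = a, 1 = s); the
    returned values are the other coordinate of each crossing, sorted.
    Crossings are computed edge-by-edge, counting each boundary crossing
    once (vertices lying exactly on the line are attributed to the edge
    whose interior crosses the level; an edge collinear with the line
    contributes its two endpoints).
    """
    mn, mx = contour.vertices[:, axis].min(), contour.vertices[:, axis].max()
    if not (mn <= level <= mx):
        return np.array([])
    line_span = max(abs(contour.vertices[:, 1 - axis]).max() * 2 + 1000.0, 1000.0)
    if axis == 1:  # horizontal line, varying a
        line = LineString([(-line_span, level), (line_span, level)])
    else:
        line = LineString([(level, -line_span), (level, line_span)])
    inter = contour.polygon.boundary.intersection(line)
    coords: list[float] = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.is_empty:
            continue
        if g.geom_type == "Point":
            coords.append(g.x if axis == 1 else g.y)
        else:  # collinear segment: keep its endpoints
            xs = np.asarray(g.coords)
            vals = xs[:, 0] if axis == 1 else xs[:, 1]
            coords.extend([vals.min(), vals.max()])
    return np.unique(np.asarray(sorted(coords), dtype=float))


def superellipse(center: Point2D, ra: float, rs: float, exponent: float = 2.0,
                 n_vertices: int = 64, rotation: float = 0.0) -> Contour:
    """A smooth star-convex polygon |x/ra|^p + |y/rs|^p = 1 sampled at n vertices.

    exponent 2 gives an ellipse; larger exponents approach a rectangle.
    """
    if ra <= 0 or rs <= 0 or exponent <= 0:
        raise GeometryError("superellipse radii and exponent must be positive")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = ra * np.sign(ct) * np.abs(ct) ** (2.0 / exponent)
    y = rs * np.sign(st) * np.abs(st) ** (2.0 / exponent)
    if rotation:
        cr, sr = np.cos(rotation), np.sin(rotation)
        x, y = cr * x - sr * y, sr * x + cr * y
    return Contour(np.column_stack([x + center.a, y + center.s]))
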