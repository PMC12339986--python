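"""Observation windows, marked point patterns and edge-correction geometry.

The unit of analysis is a planar marked point pattern inside a polygonal
observation window (a photogrammetry transect footprint, coordinates in
metres). All second-order statistics in :mod:`sppa.summaries` route their
edge correction through :func:`isotropic_weight`, Ripley's isotropic
correction: the reciprocal of the fraction of the circle through the
neighbour whose circumference lies inside the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

__all__ = [
    "ObservationWindow",
    "PointPattern",
    "NNDSummary",
    "InvalidGeometryError",
    "InsufficientPointsError",
    "polygon_area",
    "nnd_summary",
    "isotropic_weight",
    "intensity_estimate_scalar",
]


class InvalidGeometryError(ValueError):
    """Raised for self-intersecting, unclosed or degenerate window rings."""


class InsufficientPointsError(ValueError):
    """Raised when an operation needs more points than the pattern has."""


@dataclass(frozen=True)
class ObservationWindow:
    """Polygonal transect footprint in metres.

    Parameters
    ----------
    vertices : array-like of shape (k, 2)
        Ordered ring of planar coordinates. The ring may be given open or
        closed; it is stored open. Must form a simple polygon of positive
        area.
    """

    vertices: tuple = field()

    def __init__(self, vertices):
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise InvalidGeometryError("window ring needs >= 3 planar vertices")
        if not np.all(np.isfinite(verts)):
            raise InvalidGeometryError("non-finite window vertex")
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise InvalidGeometryError("degenerate window ring")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidGeometryError("window ring is self-intersecting or degenerate")
        object.__setattr__(self, "vertices", tuple(map(tuple, verts)))
        object.__setattr__(self, "_polygon", poly)
        object.__setattr__(self, "_prepared", prep(poly))

    @classmethod
    def rectangle(cls, xmin, ymin, xmax, ymax) -> "ObservationWindow":
        return cls([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        return self._polygon.area

    @property
    def bbox(self):
        """(xmin, xmax, ymin, ymax) in metres."""
        xmin, ymin, xmax, ymax = self._polygon.bounds
        return (xmin, xmax, ymin, ymax)

    @property
    def shortest_edge(self) -> float:
        """Shorter side of the bounding box; half of it is the SPPA scale."""
        xmin, xmax, ymin, ymax = self.bbox
        return min(xmax - xmin, ymax - ymin)

    @property
    def is_rectangle(self) -> bool:
        """True when the ring is exactly its axis-aligned bounding box."""
        xmin, xmax, ymin, ymax = self.bbox
        return np.isclose(self.area, (xmax - xmin) * (ymax - ymin))

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-in-window test; boundary points count as inside."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if self.is_rectangle:
            xmin, xmax, ymin, ymax = self.bbox
            return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        return np.array(
            [self._prepared.covers(Point(xi, yi)) for xi, yi in zip(x, y)]
        )

    def to_wkt(self) -> str:
        return self._polygon.wkt


def polygon_area(window: ObservationWindow) -> float:
    """Window area in square metres (shoelace value of the ring)."""
    return window.area


@dataclass(frozen=True)
class PointPattern:
    """Marked planar point set inside an observation window.

    ``marks`` is an optional per-point taxon label drawn from ``mark_levels``
    (e.g. ``"Pennatuloidea"``, ``"Cerianthidae"``, ``"Hyalonema"``).
    Points exactly on the window boundary count as inside; duplicate
    coordinates are rejected unless ``allow_duplicates=True`` because they
    usually indicate annotation errors.
    """

    x: np.ndarray
    y: np.ndarray
    window: ObservationWindow
    marks: tuple | None = None
    mark_levels: tuple | None = None

    def __init__(self, x, y, window, marks=None, mark_levels=None,
                 allow_duplicates=False):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite coordinates")
        inside = window.contains(x, y)
        if len(x) and not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise ValueError(f"points outside the window at indices {bad.tolist()}")
        if len(x) > 1:
            order = np.lexsort((y, x))
            dup = (np.diff(x[order]) == 0) & (np.diff(y[order]) == 0)
            if np.any(dup):
                if not allow_duplicates:
                    raise ValueError(
                        "duplicate coordinates (likely annotation errors); "
                        "pass allow_duplicates=True to keep them"
                    )
                warnings.warn("pattern contains duplicate coordinates")
        if marks is not None:
            marks = tuple(str(m) for m in marks)
            if len(marks) != len(x):
                raise ValueError("marks length must match point count")
            if mark_levels is None:
                mark_levels = tuple(dict.fromkeys(marks))
            else:
                mark_levels = tuple(mark_levels)
                unknown = set(marks) - set(mark_levels)
                if unknown:
                    raise ValueError(f"marks outside declared label set: {sorted(unknown)}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "window", window)
        object.__setattr__(self, "marks", marks)
        object.__setattr__(self, "mark_levels", mark_levels)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, mark: str) -> "PointPattern":
        """Unmarked sub-pattern of the points carrying ``mark``."""
        if self.marks is None:
            raise ValueError("pattern is unmarked")
        if self.mark_levels and mark not in self.mark_levels:
            raise ValueError(f"mark {mark!r} not in label set {self.mark_levels}")
        keep = np.array([m == mark for m in self.marks])
        return PointPattern(self.x[keep], self.y[keep], self.window,
                            allow_duplicates=True)

    def unmarked(self) -> "PointPattern":
        """The superposition pattern with marks dropped."""
        return PointPattern(self.x, self.y, self.window, allow_duplicates=True)

    def counts_by_mark(self) -> dict:
        if self.marks is None:
            return {}
        out = {m: 0 for m in (self.mark_levels or ())}
        for m in self.marks:
            out[m] = out.get(m, 0) + 1
        return out


@dataclass(frozen=True)
class NNDSummary:
    """Per-point nearest-neighbour distances with min and mean (metres).

    Raw (not edge-corrected) distances, matching how transect summary tables
    report them.
    """

    distances: np.ndarray
    min: float
    mean: float


def nnd_summary(pattern: PointPattern) -> NNDSummary:
    """Nearest-neighbour distance summary over all points, ignoring marks."""
    if pattern.n < 2:
        raise InsufficientPointsError("nearest-neighbour summary needs n >= 2")
    from scipy.spatial import cKDTree

    tree = cKDTree(pattern.coords)
    d, _ = tree.query(pattern.coords, k=2)
    distances = d[:, 1]
    if np.any(distances == 0):
        warnings.warn("zero nearest-neighbour distance (duplicate coordinates)")
    return NNDSummary(distances=distances, min=float(distances.min()),
                      mean=float(distances.mean()))


def intensity_estimate_scalar(pattern: PointPattern) -> float:
    """Uniform intensity estimate n/|W| in individuals per square metre."""
    return pattern.n / pattern.window.area


# ---------------------------------------------------------------------------
# Ripley's isotropic edge correction
# ---------------------------------------------------------------------------

def _rect_inside_fraction(x, y, r, xmin, xmax, ymin, ymax):
    """Fraction of circle circumference inside an axis-aligned rectangle.

    Vectorised closed form: each side closer than r cuts an arc of half-width
    arccos(d/r); adjacent arcs overlap exactly when the corner lies inside
    the circle, with overlap (a1 + a2 - pi/2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = np.asarray(r, float)
    d = np.stack([x - xmin, xmax - x, y - ymin, ymax - y])  # L, R, B, T
    with np.errstate(invalid="ignore"):
        a = np.arccos(np.clip(d / r, -1.0, 1.0))
    a = np.where(d < r, a, 0.0)
    outside = 2.0 * a.sum(axis=0)
    # corners: (L,B), (L,T), (R,B), (R,T)
    for h, v in ((0, 2), (0, 3), (1, 2), (1, 3)):
        overlap = a[h] + a[v] - 0.5 * np.pi
        outside -= np.where(overlap > 0, overlap, 0.0)
    return 1.0 - outside / (2.0 * np.pi)


def _polygon_inside_fraction(px, py, r, window: ObservationWindow) -> float:
    """Fraction of the circle of radius r at (px, py) inside a simple polygon.

    Exact up to float precision for any simple ring: circle-segment
    intersections give the candidate arc boundaries; each arc is classified
    by a point-in-polygon test at its midpoint.
    """
    verts = np.asarray(window.vertices, float)
    a = verts
    b = np.roll(verts, -1, axis=0)
    c = np.array([px, py])
    angles = []
    for p0, p1 in zip(a, b):
        d = p1 - p0
        f = p0 - c
        A = d @ d
        B = 2 * (f @ d)
        C = f @ f - r * r
        disc = B * B - 4 * A * C
        if A == 0 or disc < 0:
            continue
        sq = np.sqrt(disc)
        for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
            if -1e-12 <= t <= 1 + 1e-12:
                q = p0 + np.clip(t, 0, 1) * d
                angles.append(np.arctan2(q[1] - c[1], q[0] - c[0]))
    if not angles:
        # no boundary crossing: circle entirely inside or entirely outside
        probe = Point(px + r, py)
        return 1.0 if window._prepared.covers(probe) else 0.0
    angles = np.sort(np.mod(angles, 2 * np.pi))
    angles = np.concatenate([angles, [angles[0] + 2 * np.pi]])
    inside = 0.0
    for lo, hi in zip(angles[:-1], angles[1:]):
        mid = 0.5 * (lo + hi)
        probe = Point(px + r * np.cos(mid), py + r * np.sin(mid))
        if window._prepared.covers(probe):
            inside += hi - lo
    return inside / (2 * np.pi)


def isotropic_weight(point, r, window: ObservationWindow) -> float:
    """Ripley isotropic edge-correction weight at ``point`` for radius ``r``.

    Returns 1 / (fraction of the circumference of the circle of radius r
    centred at ``point`` lying inside the window); 1 for a fully interior
    circle, 2 for a point on a straight edge, 4 at a right-angled corner.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    px, py = float(point[0]), float(point[1])
    if not window.contains(px, py)[0]:
        raise ValueError("point must lie inside the window")
    if window.is_rectangle:
        xmin, xmax, ymin, ymax = window.bbox
        frac = float(_rect_inside_fraction(px, py, r, xmin, xmax, ymin, ymax))
    else:
        frac = _polygon_inside_fraction(px, py, r, window)
    if frac <= 1e-12:
        raise ValueError("circle lies entirely outside the window; weight undefined")
    return 1.0 / frac


def pair_weights(pattern: PointPattern, d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Isotropic weights w(x_i, d_ij) for an array of (point index, distance).

    Fast vectorised path for rectangular windows; per-pair exact arc
    computation otherwise.
    """
    w = np.empty(len(d), float)
    win = pattern.window
    if win.is_rectangle:
        xmin, xmax, ymin, ymax = win.bbox
        frac = _rect_inside_fraction(pattern.x[idx], pattern.y[idx], d,
                                     xmin, xmax, ymin, ymax)
        np.clip(frac, 1e-12, None, out=frac)
        w[:] = 1.0 / frac
    else:
        for k in range(len(d)):
            w[k] = isotropic_weight((pattern.x[idx[k]], pattern.y[idx[k]]),
                                    d[k], win)
    return w
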