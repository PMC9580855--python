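"""Geometric selection primitives and measurement tools.

These are the headless counterparts of the in-VR tools: selecting points
with a sphere, a convex hull spanned by landmarks, a clipping plane or a
column threshold; combining selections with set algebra; measuring
distances and angles; counting; and profiling the cloud along a segment
as a bin count.

All selections are *closed*: points exactly on a boundary are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cloud_io import PointCloud

HULL_TOL = 1e-9  # inner-side tolerance for facet half-space tests


# ---------------------------------------------------------------------------
# selection shapes
# ---------------------------------------------------------------------------

@dataclass
class Sphere:
    """Closed ball: keeps points with ``||p - center|| <= radius``."""
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d2 = np.sum((points - self.center) ** 2, axis=1)
        return d2 <= self.radius ** 2

    def to_dict(self) -> dict:
        return {"shape": "sphere", "center": self.center.tolist(),
                "radius": self.radius}


@dataclass
class Hull:
    """Convex hull of user-placed landmarks (at least 4, not coplanar)."""
    landmarks: np.ndarray
    _equations: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.landmarks = np.atleast_2d(np.asarray(self.landmarks, dtype=float))
        if len(self.landmarks) < 4:
            raise ValueError("hull needs at least 4 landmarks")
        try:
            hull = ConvexHull(self.landmarks)
        except QhullError as err:
            raise ValueError(f"degenerate hull landmarks: {err}") from err
        self._equations = hull.equations  # rows [a b c d]: a.x + d <= 0 inside

    def contains(self, points: np.ndarray) -> np.ndarray:
        vals = points @ self._equations[:, :3].T + self._equations[:, 3]
        return np.all(vals <= HULL_TOL, axis=1)

    def to_dict(self) -> dict:
        return {"shape": "hull", "landmarks": self.landmarks.tolist()}


@dataclass
class Plane:
    """Clipping plane keeping one closed half-space.

    ``keep_side=+1`` keeps points with ``(p - point) . normal >= 0``,
    ``-1`` the opposite side; points exactly on the plane are kept.
    """
    point: np.ndarray
    normal: np.ndarray
    keep_side: int = +1

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1.0) > 1e-9:
            if nrm == 0:
                raise ValueError("plane normal must be nonzero")
            self.normal = self.normal / nrm
        if self.keep_side not in (+1, -1):
            raise ValueError("keep_side must be +1 or -1")

    def contains(self, points: np.ndarray) -> np.ndarray:
        s = (points - self.point) @ self.normal
        return self.keep_side * s >= 0

    def to_dict(self) -> dict:
        return {"shape": "plane", "point": self.point.tolist(),
                "normal": self.normal.tolist(), "keep_side": self.keep_side}


@dataclass
class Threshold:
    """Keep points whose column value lies in the closed range [min, max]."""
    column: str
    min: float = -np.inf
    max: float = np.inf

    def to_dict(self) -> dict:
        return {"shape": "threshold", "column": self.column,
                "min": float(self.min), "max": float(self.max)}


SelectionShape = Sphere | Hull | Plane | Threshold


def shape_from_dict(d: dict) -> SelectionShape:
    """Rebuild a selection shape from its JSON dictionary."""
    kind = d.get("shape")
    if kind == "sphere":
        return Sphere(d["center"], d["radius"])
    if kind == "hull":
        return Hull(np.asarray(d["landmarks"]))
    if kind == "plane":
        return Plane(d["point"], d["normal"], d.get("keep_side", +1))
    if kind == "threshold":
        return Threshold(d["column"], d.get("min", -np.inf), d.get("max", np.inf))
    raise ValueError(f"unknown shape kind {kind!r}")


def shape_to_json(shape: SelectionShape) -> str:
    return json.dumps(shape.to_dict())


def shape_from_json(s: str) -> SelectionShape:
    return shape_from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# selection and combination
# ---------------------------------------------------------------------------

def select(cloud: PointCloud, shape: SelectionShape) -> np.ndarray:
    """Indices of cloud points captured by ``shape`` (sorted, unique)."""
    if isinstance(shape, Threshold):
        if shape.column == "t":
            vals = cloud.time
        elif shape.column in cloud.columns:
            vals = cloud.columns[shape.column]
        else:
            raise KeyError(f"no column {shape.column!r} in cloud")
        mask = (vals >= shape.min) & (vals <= shape.max)
    else:
        mask = shape.contains(cloud.positions)
    return np.flatnonzero(mask)


def combine(selections: Sequence[np.ndarray], mode: str) -> np.ndarray:
    """Set algebra on index sets: union, intersection, or difference.

    ``difference`` removes every later set from the first one.
    """
    if len(selections) == 0:
        raise ValueError("combine needs at least one selection")
    sets = [np.unique(np.asarray(s, dtype=int)) for s in selections]
    out = sets[0]
    for s in sets[1:]:
        if mode == "union":
            out = np.union1d(out, s)
        elif mode == "intersection":
            out = np.intersect1d(out, s)
        elif mode == "difference":
            out = np.setdiff1d(out, s)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# measurement tools
# ---------------------------------------------------------------------------

def measure_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two landmarks."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p2 - p1))


def measure_angle(a: Sequence[float], vertex: Sequence[float],
                  b: Sequence[float]) -> float:
    """Angle at ``vertex`` between arms to ``a`` and ``b``, in degrees."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float)
    u, w = a - v, b - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ValueError("zero-length angle arm")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def count(selection: Sequence[int]) -> int:
    """Number of distinct selected points."""
    return int(len(np.unique(np.asarray(selection, dtype=int))))


# ---------------------------------------------------------------------------
# segment profile
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    """Bin counts of the cloud along a segment (optionally within a tube)."""
    p1: np.ndarray
    p2: np.ndarray
    edges: np.ndarray   # n_bins+1 parameters along [0, 1]
    counts: np.ndarray
    radius: float | None = None


def segment_profile(cloud: PointCloud, p1: Sequence[float], p2: Sequence[float],
                    n_bins: int, radius: float | None = None) -> ProfileResult:
    """Profile the point cloud along the segment p1 -> p2 as a bin count.

    Each point is projected onto the segment axis; points whose projection
    parameter lies in [0, 1] (and, when ``radius`` is given, whose
    perpendicular distance is at most ``radius``) are histogrammed into
    ``n_bins`` equal intervals.  The last bin is right-closed so the total
    count is conserved.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p1 = np.asarray(p1, dtype=float).reshape(3)
    p2 = np.asarray(p2, dtype=float).reshape(3)
    axis = p2 - p1
    L2 = float(axis @ axis)
    if L2 == 0:
        raise ValueError("profile segment endpoints coincide")
    rel = cloud.positions - p1
    t = rel @ axis / L2
    keep = (t >= 0.0) & (t <= 1.0)
    if radius is not None:
        perp = rel - np.outer(t, axis)
        keep &= np.linalg.norm(perp, axis=1) <= radius
    tk = t[keep]
    # floor into bins; parameter exactly 1 folds into the last bin
    bins = np.minimum((tk * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return ProfileResult(p1, p2, edges, counts, radius)
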