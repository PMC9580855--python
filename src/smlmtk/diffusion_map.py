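"""3D diffusivity / force mapping on a k-means tessellation.

The mapping pipeline assumes physical properties (diffusion coefficient,
drift, interaction potential) are constant within small spatial regions.
It proceeds in three stages:

1. the localizations are tessellated into k regions with k-means;
2. every translocation is assigned to the region containing its starting
   point, and per region the overdamped-Langevin MLE of (D, v) is run
   (flat prior, so the MAP coincides with the MLE); the force follows
   from the drift as F = v kT / D;
3. each region's border is meshed as the convex hull of its member
   points, coloured by the estimated D for export (PLY/OBJ) and colour
   mapping back onto the cloud.

Regions with too few translocations are flagged ``insufficient_data``
and carry no estimate rather than aborting the map.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .cloud_io import AnalysisRecord, PointCloud, TrajectorySet
from .dynamics import MLEResult, mle_diffusion_drift

MIN_TRANSLOCATIONS = 20  # below this a region reports no estimate


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """k-means tessellation of the localization positions."""
    k: int
    labels: np.ndarray   # (N,) region index per point
    centers: np.ndarray  # (k, 3)
    seed: int
    inertia: float = 0.0

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest-center region index for arbitrary positions."""
        points = np.atleast_2d(points)
        d2 = ((points[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def partition_kmeans(positions: np.ndarray, k: int | None = None,
                     points_per_region: int | None = None, seed: int = 0,
                     max_iter: int = 300, n_init: int = 10) -> RegionPartition:
    """Tessellate positions into k regions with (seeded) Lloyd k-means.

    Either ``k`` or ``points_per_region`` must be given; in the latter
    case ``k = max(1, round(N / points_per_region))``.  Initialization is
    k-means++ with ``n_init`` restarts; a fixed seed gives identical
    labels and centers on every run.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if points_per_region is not None:
        if k is not None:
            raise ValueError("give either k or points_per_region, not both")
        k = max(1, round(n / points_per_region))
    if k is None:
        raise ValueError("either k or points_per_region is required")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, random_state=seed, max_iter=max_iter,
                n_init=n_init, init="k-means++")
    labels = km.fit_predict(positions)
    return RegionPartition(k, labels.astype(int), km.cluster_centers_,
                           seed, float(km.inertia_))


def assign_translocations(trajectories: TrajectorySet,
                          partition: RegionPartition
                          ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Group translocations by the region of their starting point.

    Returns region index -> ``(dr (M,3), dt (M,))``; every region of the
    partition appears, possibly with empty arrays.
    """
    per_region: dict[int, tuple[list, list]] = \
        {r: ([], []) for r in range(partition.k)}
    for tr in trajectories:
        if len(tr) < 2:
            continue
        dr, dt = tr.translocations
        start_labels = partition.assign(tr.positions[:-1])
        for r in np.unique(start_labels):
            sel = start_labels == r
            per_region[int(r)][0].append(dr[sel])
            per_region[int(r)][1].append(dt[sel])
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for r, (drs, dts) in per_region.items():
        if drs:
            out[r] = (np.concatenate(drs), np.concatenate(dts))
        else:
            out[r] = (np.empty((0, 3)), np.empty(0))
    return out


# ---------------------------------------------------------------------------
# per-region inference
# ---------------------------------------------------------------------------

@dataclass
class RegionEstimate:
    """Inferred local physics of one region."""
    region: int
    D: float | None              # um^2/s
    v: np.ndarray | None         # drift, um/s
    F: np.ndarray | None         # force, kT/um (v * kT / D)
    n_translocations: int
    logL: float | None
    status: str                  # ok | insufficient_data | boundary


@dataclass
class DiffusionMap:
    """Partition plus per-region (D, v, F) estimates."""
    partition: RegionPartition
    estimates: list[RegionEstimate]
    sigma: float
    kT: float

    def values(self, attr: str = "D") -> np.ndarray:
        """Per-region scalar array (NaN where no estimate)."""
        out = np.full(self.partition.k, np.nan)
        for e in self.estimates:
            val = getattr(e, attr)
            if val is not None:
                out[e.region] = val if np.isscalar(val) else np.linalg.norm(val)
        return out

    def to_record(self, created: str | None = None) -> AnalysisRecord:
        regions = []
        for e in self.estimates:
            regions.append({
                "region": e.region,
                "D": e.D,
                "v": None if e.v is None else list(e.v),
                "F": None if e.F is None else list(e.F),
                "n_translocations": e.n_translocations,
                "logL": e.logL,
                "status": e.status,
            })
        return AnalysisRecord(
            tool="map3d",
            parameters={"k": self.partition.k, "seed": self.partition.seed,
                        "sigma": self.sigma, "kT": self.kT},
            outputs={"regions": regions},
            created=created)


def infer_map(cloud: PointCloud, trajectories: TrajectorySet,
              partition: RegionPartition, sigma: float = 0.0, kT: float = 1.0,
              min_translocations: int = MIN_TRANSLOCATIONS) -> DiffusionMap:
    """Per-region MLE of (D, v) and derived force F = v kT / D.

    Appends per-point columns ``region`` and ``D_local`` to the cloud
    (NaN where the region has no estimate) so the map can be colour
    coded on the original localizations.
    """
    per_region = assign_translocations(trajectories, partition)
    estimates: list[RegionEstimate] = []
    for r in range(partition.k):
        dr, dt = per_region[r]
        m = len(dr)
        if m < max(min_translocations, 2):
            estimates.append(RegionEstimate(r, None, None, None, m, None,
                                            "insufficient_data"))
            continue
        res: MLEResult = mle_diffusion_drift(dr, dt, sigma=sigma)
        status = "boundary" if "boundary" in res.flags else "ok"
        F = res.v * kT / res.D if res.D > 0 else None
        estimates.append(RegionEstimate(r, res.D, res.v, F, m, res.logL,
                                        status))
    dmap = DiffusionMap(partition, estimates, sigma, kT)
    labels = partition.assign(cloud.positions)
    d_vals = dmap.values("D")
    cloud.columns["region"] = labels.astype(float)
    cloud.columns["D_local"] = d_vals[labels]
    return dmap


# ---------------------------------------------------------------------------
# region meshes
# ---------------------------------------------------------------------------

@dataclass
class RegionMesh:
    """Convex-hull border of one region, coloured by its scalar value."""
    region: int
    vertices: np.ndarray   # (V, 3)
    faces: np.ndarray      # (F, 3) int, triangles
    value: float
    rgba: tuple[int, int, int, int]
    render_hint: str = "surface"   # surface | wireframe

    @property
    def volume(self) -> float:
        return float(ConvexHull(self.vertices).volume)


def build_region_meshes(cloud: PointCloud, partition: RegionPartition,
                        values: np.ndarray, colormap: str = "viridis",
                        transparency: float = 1.0,
                        render_hint: str = "surface") -> list[RegionMesh]:
    """Mesh each region border as the convex hull of its member points.

    Regions with fewer than 4 points or degenerate (coplanar) geometry
    are skipped with a warning.  Colours come from ``colormap`` applied
    to min-max normalized values over the valid regions; ``transparency``
    sets the alpha channel (1 = opaque).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != partition.k:
        raise ValueError("need one value per region")
    cmap = colormaps[colormap]
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no region has a finite value")
    vmin, vmax = float(finite.min()), float(finite.max())
    span = vmax - vmin

    meshes: list[RegionMesh] = []
    alpha = int(round(np.clip(transparency, 0.0, 1.0) * 255))
    for r in range(partition.k):
        pts = cloud.positions[partition.labels == r]
        if len(pts) < 4 or not np.isfinite(values[r]):
            warnings.warn(f"region {r}: skipped ({len(pts)} points)")
            continue
        try:
            hull = ConvexHull(pts)
        except QhullError:
            warnings.warn(f"region {r}: degenerate geometry, skipped")
            continue
        used = np.unique(hull.simplices)
        remap = np.zeros(len(pts), dtype=int)
        remap[used] = np.arange(len(used))
        x = 0.5 if span == 0 else (values[r] - vmin) / span
        r_, g_, b_, _ = cmap(float(x))
        rgba = (int(round(r_ * 255)), int(round(g_ * 255)),
                int(round(b_ * 255)), alpha)
        meshes.append(RegionMesh(r, pts[used], remap[hull.simplices],
                                 float(values[r]), rgba, render_hint))
    if not meshes:
        raise ValueError("all regions degenerate; no mesh produced")
    return meshes


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def export_map(meshes: list[RegionMesh], path: str | os.PathLike,
               fmt: str | None = None) -> None:
    """Write region meshes as a single PLY (vertex RGBA) or OBJ file.

    PLY is ASCII with per-vertex ``red green blue alpha`` so colours
    round-trip byte-exact; OBJ writes one ``g region_<i>`` group per
    region (OBJ carries no colours).  ``fmt`` defaults to the file
    extension.
    """
    if not meshes:
        raise ValueError("no meshes to export")
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower() or "ply"
    if fmt == "ply":
        _write_ply(meshes, path)
    elif fmt == "obj":
        _write_obj(meshes, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def _write_ply(meshes: list[RegionMesh], path) -> None:
    n_v = sum(len(m.vertices) for m in meshes)
    n_f = sum(len(m.faces) for m in meshes)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment smlmtk diffusion map, {len(meshes)} regions\n")
        fh.write(f"element vertex {n_v}\n")
        for p in ("x", "y", "z"):
            fh.write(f"property float {p}\n")
        for c in ("red", "green", "blue", "alpha"):
            fh.write(f"property uchar {c}\n")
        fh.write(f"element face {n_f}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for m in meshes:
            r, g, b, a = m.rgba
            for v in m.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {r} {g} {b} {a}\n")
        offset = 0
        for m in meshes:
            for f in m.faces:
                fh.write(f"3 {f[0] + offset} {f[1] + offset} {f[2] + offset}\n")
            offset += len(m.vertices)


def _write_obj(meshes: list[RegionMesh], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# smlmtk diffusion map, {len(meshes)} regions\n")
        offset = 1  # OBJ indices are 1-based
        for m in meshes:
            fh.write(f"g region_{m.region}\n")
            for v in m.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in m.faces:
                fh.write(f"f {f[0] + offset} {f[1] + offset} {f[2] + offset}\n")
            offset += len(m.vertices)
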