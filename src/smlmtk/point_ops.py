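"""Point-cloud analyses that add a column or build a new cloud.

Two standard SMLM post-processing steps:

* **local density** — per-point density estimate, either from the
  distance to the k-th nearest neighbour or from a fixed-radius count,
  appended as a new cloud column for colour mapping;
* **blinking merge** — fluorophores blink, so one molecule yields a
  burst of localizations over consecutive frames.  Localizations closer
  than ``eps`` in space and ``max_gap`` in time are linked, and each
  connected component of the link graph collapses to one merged point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .cloud_io import PointCloud

_SPHERE = 4.0 / 3.0 * np.pi


@dataclass
class DensityResult:
    """Per-point local densities (points per unit volume)."""
    density: np.ndarray
    mode: str                 # "knn" | "radius"
    parameter: float          # k or R


def local_density(cloud: PointCloud, mode: str = "knn",
                  k: int | None = None, R: float | None = None,
                  strict: bool = True) -> DensityResult:
    """Estimate the local point density around every localization.

    ``knn`` mode: ``d_i = k / (4/3 pi r_k^3)`` with ``r_k`` the distance
    to the k-th nearest neighbour (the point itself excluded).  ``radius``
    mode: ``d_i = n_i / (4/3 pi R^3)`` with ``n_i`` the neighbours within
    ``R``, self excluded.  No edge correction is applied, so densities
    near the cloud boundary are biased low.

    With ``strict`` (default) a duplicate point that makes ``r_k = 0``
    raises; otherwise its density is reported as ``inf``.
    """
    n = len(cloud)
    tree = cKDTree(cloud.positions)
    if mode == "knn":
        if k is None or k < 1:
            raise ValueError("knn mode requires k >= 1")
        if n <= k:
            raise ValueError(f"knn mode needs more than k={k} points, have {n}")
        dist, _ = tree.query(cloud.positions, k=k + 1)
        r_k = dist[:, k]
        if np.any(r_k == 0):
            if strict:
                i = int(np.flatnonzero(r_k == 0)[0])
                raise ValueError(
                    f"point {i} has {k} coincident neighbours (r_k = 0); "
                    "pass strict=False to report inf")
            with np.errstate(divide="ignore"):
                density = np.where(r_k > 0, k / (_SPHERE * r_k ** 3), np.inf)
        else:
            density = k / (_SPHERE * r_k ** 3)
        return DensityResult(density, "knn", float(k))
    if mode == "radius":
        if R is None or R <= 0:
            raise ValueError("radius mode requires R > 0")
        counts = np.asarray(
            tree.query_ball_point(cloud.positions, R, return_length=True),
            dtype=float) - 1.0  # self excluded
        density = counts / (_SPHERE * R ** 3)
        return DensityResult(density, "radius", float(R))
    raise ValueError(f"unknown density mode {mode!r}")


@dataclass
class MergedCloud:
    """Result of collapsing blinking bursts into one point per molecule."""
    positions: np.ndarray          # (M, 3) merged centroids
    counts: np.ndarray             # source localizations per merged point
    first_time: np.ndarray
    last_time: np.ndarray
    mean_intensity: np.ndarray | None
    members: list[np.ndarray]      # source indices per merged point
    labels: np.ndarray             # (N,) merged-point id per source row

    @property
    def n_merged(self) -> int:
        return len(self.positions)

    def to_cloud(self) -> PointCloud:
        cols = {
            "count": self.counts.astype(float),
            "first_t": self.first_time,
            "last_t": self.last_time,
        }
        if self.mean_intensity is not None:
            cols["intensity"] = self.mean_intensity
        return PointCloud(self.positions, self.first_time, cols)


def merge_blinking(cloud: PointCloud, eps: float, max_gap: float,
                   intensity_weighted: bool = False,
                   intensity_column: str = "intensity") -> MergedCloud:
    """Merge localizations produced by one blinking molecule.

    Two localizations are linked when their spatial distance is at most
    ``eps`` and their time gap is positive and at most ``max_gap``
    (localizations in the *same* frame are never linked directly: one
    molecule emits at most once per frame).  Merged points are the
    connected components of the link graph, so a slowly drifting blink
    chain with short gaps merges into a single point even if its total
    span exceeds ``max_gap``.

    The merged position is the unweighted centroid of the component, or
    the intensity-weighted centroid when ``intensity_weighted`` is set
    and the intensity column exists.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    n = len(cloud)
    if n == 0:
        return MergedCloud(np.empty((0, 3)), np.empty(0, int), np.empty(0),
                           np.empty(0), None, [], np.empty(0, int))

    tree = cKDTree(cloud.positions)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    if len(pairs):
        gap = np.abs(cloud.time[pairs[:, 0]] - cloud.time[pairs[:, 1]])
        pairs = pairs[(gap > 0) & (gap <= max_gap)]
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, comp = sparse.csgraph.connected_components(graph, directed=False)

    # relabel components by first appearance so output order is stable
    order = np.zeros(n_comp, dtype=int)
    seen = np.full(n_comp, -1, dtype=int)
    nxt = 0
    for lab in comp:
        if seen[lab] < 0:
            seen[lab] = nxt
            nxt += 1
    labels = seen[comp]

    intens = cloud.columns.get(intensity_column)
    weights = None
    if intensity_weighted:
        if intens is None:
            raise KeyError(f"no column {intensity_column!r} for weighting")
        weights = intens

    positions = np.empty((n_comp, 3))
    counts = np.empty(n_comp, dtype=int)
    first_t = np.empty(n_comp)
    last_t = np.empty(n_comp)
    mean_int = np.empty(n_comp) if intens is not None else None
    members: list[np.ndarray] = [np.empty(0, int)] * n_comp
    idx_sorted = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[idx_sorted], np.arange(n_comp + 1))
    for m in range(n_comp):
        mem = idx_sorted[bounds[m]:bounds[m + 1]]
        members[m] = np.sort(mem)
        counts[m] = len(mem)
        if weights is not None and weights[mem].sum() > 0:
            w = weights[mem] / weights[mem].sum()
            positions[m] = w @ cloud.positions[mem]
        else:
            positions[m] = cloud.positions[mem].mean(axis=0)
        first_t[m] = cloud.time[mem].min()
        last_t[m] = cloud.time[mem].max()
        if mean_int is not None:
            mean_int[m] = intens[mem].mean()
    return MergedCloud(positions, counts, first_t, last_t, mean_int,
                       members, labels)
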