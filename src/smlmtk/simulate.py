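"""Synthetic SMLM data: trajectories and blinking localizations.

Generators for the two kinds of experimental input the toolkit analyses:

* **tracked particles** — overdamped-Langevin walks (Euler–Maruyama),
  optionally with drift, a heterogeneous diffusivity landscape with
  harmonic trapping wells, reflecting box walls and static localization
  noise; and fractional Brownian motion for anomalous diffusion;
* **blinking emitters** — fixed molecules switching through a two-state
  (on/off) Markov chain with an absorbing bleached state, emitting one
  noisy localization per on-frame.

Every generator takes a ``seed`` and draws from its own
``numpy.random.default_rng`` stream, so outputs are bit-reproducible.
Defaults mirror a nuclear bead-tracking experiment: 30 ms frame
interval, diffusivities of order 0.1–1 um^2/s, localization precision
of a few tens of nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud_io import PointCloud, Trajectory, TrajectorySet

DEFAULT_DT = 0.03     # s, 30 ms exposure
DEFAULT_D = 0.5       # um^2/s, free nuclear bead scale


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold positions back into [lo, hi] by mirror reflection."""
    span = hi - lo
    p = np.mod(pos - lo, 2 * span)
    p = np.where(p > span, 2 * span - p, p)
    return lo + p


# ---------------------------------------------------------------------------
# homogeneous Brownian walks
# ---------------------------------------------------------------------------

def simulate_brownian(n_trajectories: int, n_steps: int, dt: float = DEFAULT_DT,
                      D: float = DEFAULT_D, v=(0.0, 0.0, 0.0),
                      sigma: float = 0.0,
                      box: tuple | None = None,
                      seed: int = 0) -> TrajectorySet:
    """Brownian trajectories with optional constant drift and noise.

    Each step is ``dr = v dt + sqrt(2 D dt) eta`` with eta standard 3D
    Gaussian; measurement noise (sd ``sigma``) is added to the recorded
    positions afterwards, so consecutive steps pick up the static-error
    correlation real localization data shows.  ``box`` is
    ``((xlo,ylo,zlo), (xhi,yhi,zhi))``; walls reflect.  Without a box,
    walks start at the origin.
    """
    if dt <= 0 or D < 0 or sigma < 0:
        raise ValueError("dt must be > 0, D and sigma >= 0")
    rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float).reshape(3)
    lo = hi = None
    if box is not None:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
    trajectories = []
    times = np.arange(n_steps + 1) * dt
    scale = np.sqrt(2 * D * dt)
    for i in range(n_trajectories):
        start = rng.uniform(lo, hi) if box is not None else np.zeros(3)
        steps = v * dt + scale * rng.standard_normal((n_steps, 3))
        pos = np.empty((n_steps + 1, 3))
        pos[0] = start
        if box is None:
            pos[1:] = start + np.cumsum(steps, axis=0)
        else:
            cur = start
            for j in range(n_steps):
                cur = _reflect(cur + steps[j], lo, hi)
                pos[j + 1] = cur
        if sigma > 0:
            pos = pos + sigma * rng.standard_normal(pos.shape)
        trajectories.append(Trajectory(float(i), pos, times.copy()))
    return TrajectorySet(trajectories)


# ---------------------------------------------------------------------------
# heterogeneous landscapes
# ---------------------------------------------------------------------------

@dataclass
class LandscapeRegion:
    """Axis-aligned box region with its own D and optional harmonic well.

    The well exerts ``F = -stiffness (r - well_center)`` (kT/um), which
    enters the overdamped dynamics as drift ``D F dt / kT``.
    """
    bounds: tuple          # ((xlo,ylo,zlo), (xhi,yhi,zhi))
    D: float
    well_center: np.ndarray | None = None
    stiffness: float = 0.0

    def __post_init__(self):
        self.lo = np.asarray(self.bounds[0], dtype=float)
        self.hi = np.asarray(self.bounds[1], dtype=float)
        if self.well_center is not None:
            self.well_center = np.asarray(self.well_center, dtype=float)

    def contains(self, p: np.ndarray) -> bool:
        return bool(np.all(p >= self.lo) and np.all(p <= self.hi))


def simulate_landscape(regions: list[LandscapeRegion], n_trajectories: int,
                       n_steps: int, dt: float = DEFAULT_DT,
                       sigma: float = 0.0, kT: float = 1.0,
                       box: tuple | None = None,
                       seed: int = 0) -> tuple[TrajectorySet, list[np.ndarray]]:
    """Walks through a piecewise-constant diffusivity/force landscape.

    Each step uses the D and force of the region containing the current
    position (first matching region wins); a position outside every
    region raises.  The outer ``box`` defaults to the union bounding box
    of the regions; walls reflect.  Returns the trajectory set and, per
    trajectory, the true region index of every recorded position — the
    ground truth for partition-recovery tests.
    """
    if not regions:
        raise ValueError("need at least one region")
    if box is None:
        lo = np.min([r.lo for r in regions], axis=0)
        hi = np.max([r.hi for r in regions], axis=0)
    else:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps + 1) * dt

    def region_of(p: np.ndarray) -> int:
        for ri, reg in enumerate(regions):
            if reg.contains(p):
                return ri
        raise ValueError(f"position {p} not covered by any region")

    trajectories, labels = [], []
    for i in range(n_trajectories):
        pos = np.empty((n_steps + 1, 3))
        lab = np.empty(n_steps + 1, dtype=int)
        cur = rng.uniform(lo, hi)
        pos[0] = cur
        lab[0] = region_of(cur)
        for j in range(n_steps):
            reg = regions[lab[j]]
            drift = np.zeros(3)
            if reg.well_center is not None and reg.stiffness != 0.0:
                F = -reg.stiffness * (cur - reg.well_center)
                drift = reg.D * F * dt / kT
            step = drift + np.sqrt(2 * reg.D * dt) * rng.standard_normal(3)
            cur = _reflect(cur + step, lo, hi)
            pos[j + 1] = cur
            lab[j + 1] = region_of(cur)
        if sigma > 0:
            pos = pos + sigma * rng.standard_normal(pos.shape)
        trajectories.append(Trajectory(float(i), pos, times.copy()))
        labels.append(lab)
    return TrajectorySet(trajectories), labels


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------

MAX_FBM_STEPS = 5000  # dense covariance factorization ceiling


def _fgn_cholesky(alpha: float, n_steps: int) -> np.ndarray:
    """Cholesky factor of the fractional-Gaussian-noise covariance.

    The increment autocovariance of fBm with MSD ~ tau^alpha
    (Hurst H = alpha/2) is
    ``gamma(m) = (|m+1|^alpha - 2|m|^alpha + |m-1|^alpha) / 2``.
    """
    m = np.arange(n_steps, dtype=float)
    gamma = 0.5 * (np.abs(m + 1) ** alpha - 2 * np.abs(m) ** alpha
                   + np.abs(m - 1) ** alpha)
    idx = np.abs(m[:, None] - m[None, :]).astype(int)
    cov = gamma[idx]
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(n_steps))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("fGn covariance not positive definite")


def simulate_fbm(alpha: float, scale: float, n_steps: int,
                 dt: float = DEFAULT_DT, seed: int = 0,
                 n_trajectories: int = 1) -> TrajectorySet:
    """Fractional Brownian motion with MSD = 3 scale^2 (tau/dt)^alpha.

    Each axis is an independent fBm with Hurst exponent H = alpha/2,
    generated exactly by Cholesky factorization of the increment
    covariance (so ``n_steps`` is capped at 5000).  ``scale`` is the
    per-axis step standard deviation at lag dt, in length units.
    """
    if not 0 < alpha <= 2:
        raise ValueError("alpha must be in (0, 2]")
    if n_steps > MAX_FBM_STEPS:
        raise ValueError(f"n_steps capped at {MAX_FBM_STEPS}")
    if scale <= 0 or dt <= 0:
        raise ValueError("scale and dt must be positive")
    rng = np.random.default_rng(seed)
    L = _fgn_cholesky(alpha, n_steps)
    times = np.arange(n_steps + 1) * dt
    trajectories = []
    for i in range(n_trajectories):
        eta = rng.standard_normal((n_steps, 3))
        steps = scale * (L @ eta)
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        trajectories.append(Trajectory(float(i), pos, times.copy()))
    return TrajectorySet(trajectories)


# ---------------------------------------------------------------------------
# blinking emitters
# ---------------------------------------------------------------------------

@dataclass
class BlinkingResult:
    """Simulated blinking acquisition plus its ground truth."""
    cloud: PointCloud            # localizations; time column = frame index
    molecule_ids: np.ndarray     # true molecule per localization
    n_molecules: int


def simulate_blinking(molecule_positions: np.ndarray, p_on: float,
                      p_off: float, p_bleach: float, n_frames: int,
                      sigma: float = 0.0, seed: int = 0,
                      start_on: bool = True) -> BlinkingResult:
    """Blinking/bleaching emitters imaged over ``n_frames`` frames.

    Each molecule is a three-state Markov chain sampled once per frame:
    ON emits a localization (true position + isotropic Gaussian noise of
    sd ``sigma``), then bleaches with probability ``p_bleach`` or
    switches off with probability ``p_off``; OFF switches on with
    probability ``p_on``; BLEACHED is absorbing.  Frame indices are the
    time stamps of the returned cloud.
    """
    for name, p in (("p_on", p_on), ("p_off", p_off), ("p_bleach", p_bleach)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if p_off + p_bleach > 1:
        raise ValueError("p_off + p_bleach must not exceed 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    mol = np.atleast_2d(np.asarray(molecule_positions, dtype=float))
    rng = np.random.default_rng(seed)
    positions, frames, ids = [], [], []
    for mi, true_pos in enumerate(mol):
        on = bool(start_on)
        for f in range(n_frames):
            if on:
                noise = sigma * rng.standard_normal(3) if sigma > 0 else 0.0
                positions.append(true_pos + noise)
                frames.append(float(f))
                ids.append(mi)
                u = rng.random()
                if u < p_bleach:
                    break
                on = u >= p_bleach + p_off
            else:
                on = rng.random() < p_on
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    cloud = PointCloud(pos, np.asarray(frames, dtype=float),
                       metadata={"unit": "um", "kind": "blinking"})
    return BlinkingResult(cloud, np.asarray(ids, dtype=int), len(mol))


def scattered_molecules(n_molecules: int, min_separation: float,
                        box_size: float = 10.0, seed: int = 0) -> np.ndarray:
    """Molecule positions in a cube with a guaranteed minimum separation.

    Dart-throwing (rejection) sampling; raises if the requested packing
    cannot be reached in a bounded number of throws.
    """
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_molecules:
        cand = rng.uniform(0, box_size, 3)
        if all(np.linalg.norm(cand - p) >= min_separation for p in pts):
            pts.append(cand)
        tries += 1
        if tries > 200 * n_molecules + 1000:
            raise RuntimeError("could not place molecules at that separation")
    return np.asarray(pts)
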