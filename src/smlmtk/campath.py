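"""Camera fly-through paths: waypoint files and pose interpolation.

A recording script is a list of timed waypoints — camera position, a
look-at target, how long to dwell at the waypoint and how long the
transit to the next one takes — plus optional visual parameters
(colormap, thresholds).  This module parses and writes the waypoint
format and turns a script into a uniformly sampled pose sequence
(position + orientation quaternion at a fixed frame rate) that any
renderer can consume; rendering itself is out of scope.

The primary format is JSON (``{"fps": ..., "waypoints": [...]}``); a
whitespace-separated line format (``x y z lx ly lz dwell transit`` per
line) is accepted as a secondary dialect.

Frames are sampled at ``t_i = i / fps`` with
``n = round(duration * fps)`` frames in total; the final frame clamps
to the end pose so the sequence always terminates exactly on the last
waypoint.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

UP = np.array([0.0, 0.0, 1.0])        # world up
UP_FALLBACK = np.array([0.0, 1.0, 0.0])  # used when the view is axial


@dataclass
class Waypoint:
    """One camera keyframe.

    ``transit_s`` is the time to reach the *next* waypoint and may be
    omitted (None) only on the final one; ``dwell_s`` holds the camera
    in place before departing.
    """
    position: np.ndarray
    look_at: np.ndarray
    dwell_s: float = 0.0
    transit_s: float | None = None
    visual: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.look_at = np.asarray(self.look_at, dtype=float).reshape(3)
        if np.allclose(self.position, self.look_at):
            raise ValueError("look_at must differ from position")
        if self.dwell_s < 0:
            raise ValueError("dwell_s must be non-negative")
        if self.transit_s is not None and self.transit_s <= 0:
            raise ValueError("transit_s must be positive")

    def to_dict(self) -> dict:
        d = {"position": self.position.tolist(),
             "look_at": self.look_at.tolist(),
             "dwell_s": self.dwell_s}
        if self.transit_s is not None:
            d["transit_s"] = self.transit_s
        if self.visual:
            d["visual"] = self.visual
        return d


@dataclass
class PoseSequence:
    """Uniform pose samples: times (s), positions, quaternions (w,x,y,z)."""
    times: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# smlmtk camera path\n")
            fh.write("t,x,y,z,qw,qx,qy,qz\n")
            for t, p, q in zip(self.times, self.positions, self.quaternions):
                fh.write(f"{t:.9g},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g},"
                         f"{q[0]:.9g},{q[1]:.9g},{q[2]:.9g},{q[3]:.9g}\n")


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _waypoint_from_dict(d: dict, idx: int) -> Waypoint:
    for key in ("position", "look_at"):
        if key not in d:
            raise ValueError(f"waypoint {idx}: missing field {key!r}")
        if len(d[key]) != 3:
            raise ValueError(f"waypoint {idx}: {key} must have 3 components")
    try:
        return Waypoint(d["position"], d["look_at"],
                        float(d.get("dwell_s", 0.0)),
                        None if d.get("transit_s") is None else float(d["transit_s"]),
                        dict(d.get("visual", {})))
    except ValueError as err:
        raise ValueError(f"waypoint {idx}: {err}") from err


def parse_waypoints(path: str | os.PathLike) -> tuple[list[Waypoint], dict]:
    """Read a waypoint script; returns (waypoints, global settings).

    JSON scripts carry globals (``fps``, ``colormap`` ...) next to the
    ``waypoints`` array; the line dialect has none.  Non-final waypoints
    must declare a positive ``transit_s``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("{") or stripped.startswith("["):
        doc = json.loads(text)
        if isinstance(doc, list):
            doc = {"waypoints": doc}
        raw = doc.get("waypoints")
        if not isinstance(raw, list):
            raise ValueError("JSON script must contain a 'waypoints' array")
        wps = [_waypoint_from_dict(w, i) for i, w in enumerate(raw)]
        settings = {k: v for k, v in doc.items() if k != "waypoints"}
    else:
        wps = []
        for ln, line in enumerate(text.splitlines(), start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            fields = s.split()
            if len(fields) not in (6, 7, 8):
                raise ValueError(
                    f"line {ln}: expected 6-8 fields "
                    "(x y z lx ly lz [dwell [transit]])")
            vals = [float(f) for f in fields]
            transit = vals[7] if len(vals) == 8 else None
            wps.append(Waypoint(vals[0:3], vals[3:6],
                                vals[6] if len(vals) >= 7 else 0.0, transit))
        settings = {}
    for i, w in enumerate(wps[:-1]):
        if w.transit_s is None:
            raise ValueError(f"waypoint {i}: transit_s required before "
                             "a following waypoint")
    return wps, settings


def write_waypoints(waypoints: list[Waypoint], path: str | os.PathLike,
                    **settings) -> None:
    doc = dict(settings)
    doc["waypoints"] = [w.to_dict() for w in waypoints]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _catmull_rom(P: np.ndarray, seg: int, u: float) -> np.ndarray:
    """Uniform Catmull-Rom on control points P.

    Endpoint phantoms are reflections (p_{-1} = 2 P0 - P1), which keeps
    the spline exactly linear through collinear, evenly spaced points.
    """
    n = len(P)
    p0 = 2 * P[0] - P[1] if seg == 0 else P[seg - 1]
    p1 = P[seg]
    p2 = P[min(seg + 1, n - 1)]
    p3 = 2 * P[n - 1] - P[n - 2] if seg + 2 > n - 1 else P[seg + 2]
    u2, u3 = u * u, u * u * u
    return 0.5 * ((2 * p1) + (-p0 + p2) * u
                  + (2 * p0 - 5 * p1 + 4 * p2 - p3) * u2
                  + (-p0 + 3 * p1 - 3 * p2 + p3) * u3)


def look_at_quaternion(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Quaternion (w, x, y, z) orienting a camera at ``position`` toward
    ``target``, world up +z, falling back to +y for axial views."""
    f = target - position
    nf = np.linalg.norm(f)
    if nf == 0:
        raise ValueError("look-at target coincides with position")
    f = f / nf
    up = UP if abs(f @ UP) < 1.0 - 1e-9 else UP_FALLBACK
    right = np.cross(up, f)
    right /= np.linalg.norm(right)
    true_up = np.cross(f, right)
    mat = np.column_stack([right, true_up, f])  # camera axes as columns
    q = Rotation.from_matrix(mat).as_quat()     # scipy order (x, y, z, w)
    return np.array([q[3], q[0], q[1], q[2]])


def interpolate_path(waypoints: list[Waypoint], fps: float,
                     mode: str = "linear") -> PoseSequence:
    """Sample the camera path at a fixed frame rate.

    The schedule dwells at each waypoint for its ``dwell_s`` and then
    transits to the next over its ``transit_s``; total duration is the
    sum of all dwells and transits.  Positions (and look-at targets)
    interpolate linearly or along a uniform Catmull-Rom spline through
    the waypoints; dwell frames repeat the waypoint pose exactly.
    """
    if len(waypoints) < 2:
        raise ValueError("need at least 2 waypoints")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if mode not in ("linear", "catmull_rom"):
        raise ValueError(f"unknown mode {mode!r}")

    # schedule: (t_start, t_end, kind, segment index)
    schedule = []
    t = 0.0
    for i, w in enumerate(waypoints):
        if w.dwell_s > 0:
            schedule.append((t, t + w.dwell_s, "dwell", i))
            t += w.dwell_s
        if i < len(waypoints) - 1:
            if w.transit_s is None:
                raise ValueError(f"waypoint {i}: transit_s required")
            schedule.append((t, t + w.transit_s, "transit", i))
            t += w.transit_s
    duration = t
    P = np.array([w.position for w in waypoints])
    L = np.array([w.look_at for w in waypoints])

    def pose_at(time: float) -> tuple[np.ndarray, np.ndarray]:
        time = min(max(time, 0.0), duration)
        for (t0, t1, kind, i) in schedule:
            if time <= t1 or (t0, t1, kind, i) == schedule[-1]:
                if kind == "dwell":
                    return P[i], L[i]
                u = 0.0 if t1 == t0 else (time - t0) / (t1 - t0)
                if mode == "linear":
                    return (P[i] + u * (P[i + 1] - P[i]),
                            L[i] + u * (L[i + 1] - L[i]))
                return _catmull_rom(P, i, u), _catmull_rom(L, i, u)
        return P[-1], L[-1]

    n_frames = int(round(duration * fps))
    if n_frames < 1:
        raise ValueError("path too short for one frame at this fps")
    times = np.arange(n_frames) / fps
    positions = np.empty((n_frames, 3))
    quats = np.empty((n_frames, 4))
    for i, ti in enumerate(times):
        # the last frame lands on the final pose exactly
        p, l = pose_at(duration) if i == n_frames - 1 else pose_at(ti)
        positions[i] = p
        quats[i] = look_at_quaternion(p, l)
    return PoseSequence(times, positions, quats, float(fps))
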