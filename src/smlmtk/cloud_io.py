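"""Localization-table I/O and trajectory grouping.

A *point cloud* is the table a localization pipeline emits: one row per
detected molecule, with 3D coordinates, a time stamp (seconds or frame
index) and any number of auxiliary columns (intensity, trajectory id,
computed properties).  Tables may use any single-character delimiter and
may or may not carry a header row; the reader sniffs both.

Analysis runs are persisted as JSON :class:`AnalysisRecord` objects so a
session can be reproduced from its parameters alone.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Delimiters tried, in order, when none is given.
SNIFF_DELIMITERS = ("\t", ",", ";", " ")

#: Default mapping from field names to column indices.
DEFAULT_COLUMN_MAP = {"x": 0, "y": 1, "z": 2}


class TableFormatError(ValueError):
    """Raised when a localization table violates the row format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """N localizations: 3D positions, time stamps, named extra columns.

    Parameters
    ----------
    positions
        ``(N, 3)`` array, length units (micrometre by default).
    time
        ``(N,)`` array of time stamps, seconds — or frame indices when
        ``metadata['dt']`` gives the frame interval.
    columns
        Extra per-point columns (intensity, trajectory id, densities ...).
    metadata
        Free-form provenance plus the reserved keys ``unit`` (length unit),
        ``dt`` (frame interval, s) and ``sigma`` (localization precision).
    """

    positions: np.ndarray
    time: np.ndarray | None = None
    columns: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        n = len(self.positions)
        if self.time is None:
            dt = float(self.metadata.get("dt") or 1.0)
            self.time = np.arange(n, dtype=float) * dt
        self.time = np.asarray(self.time, dtype=float)
        if self.time.shape != (n,):
            raise ValueError("time must have one entry per point")
        for name, col in list(self.columns.items()):
            col = np.asarray(col, dtype=float)
            if col.shape != (n,):
                raise ValueError(f"column {name!r} has {col.shape[0]} entries, expected {n}")
            self.columns[name] = col
        dt = self.metadata.get("dt")
        if dt is not None and dt <= 0:
            raise ValueError("dt must be positive")
        sigma = self.metadata.get("sigma")
        if sigma is not None and sigma < 0:
            raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def with_column(self, name: str, values: np.ndarray) -> "PointCloud":
        """Return a copy carrying an extra (or replaced) column."""
        cols = dict(self.columns)
        cols[name] = np.asarray(values, dtype=float)
        return PointCloud(self.positions.copy(), self.time.copy(), cols, dict(self.metadata))

    def subset(self, indices: Sequence[int]) -> "PointCloud":
        """Return the sub-cloud at ``indices`` (selection export)."""
        idx = np.asarray(indices, dtype=int)
        cols = {k: v[idx] for k, v in self.columns.items()}
        return PointCloud(self.positions[idx], self.time[idx], cols, dict(self.metadata))


@dataclass
class Trajectory:
    """One time-ordered track: positions with strictly increasing times."""

    id: float
    positions: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"trajectory {self.id}: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def translocations(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-step displacement vectors and durations ``(dr, dt)``.

        ``dr`` is ``(n-1, 3)``, ``dt`` is ``(n-1,)``; a singleton
        trajectory yields empty arrays.
        """
        return np.diff(self.positions, axis=0), np.diff(self.times)


@dataclass
class TrajectorySet:
    """A set of trajectories grouped from one localization table."""

    trajectories: list[Trajectory]

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def n_points(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def pooled_translocations(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate all translocations: ``(dr (M,3), dt (M,))``."""
        drs, dts = [], []
        for t in self.trajectories:
            dr, dt = t.translocations
            drs.append(dr)
            dts.append(dt)
        if not drs:
            return np.empty((0, 3)), np.empty(0)
        return np.concatenate(drs), np.concatenate(dts)

    def to_cloud(self, id_column: str = "trajectory") -> PointCloud:
        """Flatten back to a point cloud with an id column."""
        pos = np.concatenate([t.positions for t in self.trajectories]) \
            if self.trajectories else np.empty((0, 3))
        tim = np.concatenate([t.times for t in self.trajectories]) \
            if self.trajectories else np.empty(0)
        ids = np.concatenate([np.full(len(t), t.id, dtype=float) for t in self.trajectories]) \
            if self.trajectories else np.empty(0)
        return PointCloud(pos, tim, {id_column: ids})


@dataclass
class AnalysisRecord:
    """A reproducible log of one analysis run (tool, parameters, outputs)."""

    tool: str
    parameters: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    created: str | None = None

    @classmethod
    def new(cls, tool: str, parameters: dict | None = None,
            outputs: dict | None = None) -> "AnalysisRecord":
        """Create a record stamped with the current UTC time."""
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        return cls(tool, parameters or {}, outputs or {}, created=stamp)

    def to_dict(self) -> dict:
        return {
            "tool": self.tool,
            "parameters": _jsonify(self.parameters),
            "outputs": _jsonify(self.outputs),
            "created": self.created,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisRecord":
        return cls(d["tool"], dict(d.get("parameters", {})),
                   dict(d.get("outputs", {})), d.get("created"))


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _split(line: str, delimiter: str) -> list[str]:
    # collapse runs for whitespace delimiters, as localization tables
    # written with aligned columns commonly pad with spaces
    if delimiter == " ":
        return line.split()
    return [f.strip() for f in line.split(delimiter)]


def _sniff_delimiter(line: str) -> str:
    best, best_n = " ", 1
    for d in SNIFF_DELIMITERS:
        n = len(_split(line, d))
        if n > best_n:
            best, best_n = d, n
    return best


def read_point_cloud(path: str | os.PathLike,
                     delimiter: str | None = None,
                     column_map: Mapping[str, int] | None = None,
                     dt: float | None = None,
                     sigma: float | None = None,
                     scale: float = 1.0,
                     skip_malformed: bool = False) -> PointCloud:
    """Read a delimiter-separated localization table.

    Any single-character separator works; when ``delimiter`` is omitted it
    is sniffed from the first data line among tab, comma, semicolon and
    whitespace.  A leading header row is detected (and skipped) iff any of
    its fields fails numeric parsing; lines starting with ``#`` are
    comments.

    Parameters
    ----------
    column_map
        Field name -> zero-based column index.  Must assign at least
        ``x``, ``y``, ``z``; ``t`` maps the time column, every other name
        becomes an extra cloud column.  Defaults to the first three
        columns as x, y, z.
    dt
        Frame interval in seconds; rows lacking a time column get
        ``time = row_index * dt`` (``dt`` defaults to 1).
    sigma
        Localization precision, stored in metadata.
    scale
        Multiplier applied to coordinates on read (e.g. ``1e-3`` to turn
        nm tables into micrometres).
    skip_malformed
        If true, rows with the wrong field count are dropped instead of
        raising :class:`TableFormatError`.
    """
    column_map = dict(column_map) if column_map else dict(DEFAULT_COLUMN_MAP)
    for axis in ("x", "y", "z"):
        if axis not in column_map:
            raise ValueError(f"column_map must assign {axis!r}")

    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()

    lines: list[tuple[int, str]] = []  # (1-based line number, content)
    header_names: list[str] | None = None
    for ln, line in enumerate(raw, start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        lines.append((ln, s))

    if not lines:
        pos = np.empty((0, 3))
        meta = {"source": str(path), "unit": "um"}
        if dt is not None:
            meta["dt"] = float(dt)
        if sigma is not None:
            meta["sigma"] = float(sigma)
        extra = {n: np.empty(0) for n in column_map if n not in ("x", "y", "z", "t")}
        return PointCloud(pos, np.empty(0), extra, meta)

    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0][1])

    first_fields = _split(lines[0][1], delimiter)
    if any(not _is_number(f) for f in first_fields):
        header_names = first_fields
        lines = lines[1:]

    rows: list[list[float]] = []
    width: int | None = None
    for ln, s in lines:
        fields = _split(s, delimiter)
        if width is None:
            width = len(fields)
        if len(fields) != width or any(not _is_number(f) for f in fields):
            if skip_malformed:
                continue
            raise TableFormatError(
                f"line {ln}: expected {width} numeric fields, got "
                f"{len(fields)} ({s[:60]!r})")
        rows.append([float(f) for f in fields])

    data = np.asarray(rows, dtype=float) if rows else np.empty((0, width or 3))
    max_idx = max(column_map.values())
    if data.size and max_idx >= data.shape[1]:
        raise ValueError(
            f"column_map index {max_idx} beyond row width {data.shape[1]}")

    n = len(data)
    pos = np.column_stack([data[:, column_map[a]] for a in ("x", "y", "z")]) \
        if n else np.empty((0, 3))
    pos = pos * scale

    if "t" in column_map and n:
        time = data[:, column_map["t"]]
    else:
        time = np.arange(n, dtype=float) * (dt if dt is not None else 1.0)

    extra = {}
    for name, idx in column_map.items():
        if name in ("x", "y", "z", "t"):
            continue
        extra[name] = data[:, idx] if n else np.empty(0)

    meta: dict = {"source": str(path), "unit": "um"}
    if header_names:
        meta["header"] = header_names
    if dt is not None:
        meta["dt"] = float(dt)
    if sigma is not None:
        meta["sigma"] = float(sigma)
    return PointCloud(pos, time, extra, meta)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_point_cloud(cloud: PointCloud, path: str | os.PathLike,
                      delimiter: str = ",") -> None:
    """Write a cloud as a delimited table (positions, time, extra columns).

    The first line is a ``#`` provenance comment, the second a header row;
    ``read_point_cloud`` round-trips the numbers to 1e-9 relative.
    """
    df = pd.DataFrame({
        "x": cloud.positions[:, 0],
        "y": cloud.positions[:, 1],
        "z": cloud.positions[:, 2],
        "t": cloud.time,
    })
    for name, col in cloud.columns.items():
        df[name] = col
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# smlmtk point cloud, n={len(cloud)}, unit="
                 f"{cloud.metadata.get('unit', 'um')}\n")
        df.to_csv(fh, sep=delimiter, index=False, float_format="%.12g")


def reader_column_map(cloud: PointCloud) -> dict[str, int]:
    """Column map matching :func:`write_point_cloud` output layout."""
    cmap = {"x": 0, "y": 1, "z": 2, "t": 3}
    for i, name in enumerate(cloud.columns):
        cmap[name] = 4 + i
    return cmap


def save_record(record: AnalysisRecord, path: str | os.PathLike) -> None:
    """Serialize an analysis record to JSON (stable key order)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_record(path: str | os.PathLike) -> AnalysisRecord:
    with open(path, "r", encoding="utf-8") as fh:
        return AnalysisRecord.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# trajectory grouping
# ---------------------------------------------------------------------------

def build_trajectories(cloud: PointCloud, id_column: str = "trajectory") -> TrajectorySet:
    """Group a cloud into per-id, time-sorted trajectories.

    Singleton trajectories are kept (they simply carry no translocations).
    Duplicate ``(id, time)`` pairs make the ordering ambiguous and raise.
    """
    if id_column not in cloud.columns:
        raise KeyError(f"no column {id_column!r} in cloud "
                       f"(have {sorted(cloud.columns)})")
    ids = cloud.columns[id_column]
    trajectories = []
    for uid in np.unique(ids):
        mask = ids == uid
        times = cloud.time[mask]
        order = np.argsort(times, kind="stable")
        times = times[order]
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            bad = times[np.flatnonzero(np.diff(times) <= 0)[0]]
            raise ValueError(
                f"trajectory id {uid}: duplicate time stamp {bad} "
                "(ambiguous ordering)")
        trajectories.append(
            Trajectory(float(uid), cloud.positions[mask][order], times))
    return TrajectorySet(trajectories)
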