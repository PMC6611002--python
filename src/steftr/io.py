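"""Trajectory containers and delimited-text I/O.

Three input dialects are supported:

``planar``
    Cartesian coordinates (mm/cm/m/arbitrary units); *y* increases "up" and
    bearings are measured clockwise from +y.
``geographic``
    Longitude/latitude in degrees; step metrics are great-circle distance (m)
    and azimuth clockwise from true north.
``displacement``
    Per-sample increments (dx, dy), e.g. from a trackball sensor; increments
    are cumulatively summed to positions with origin (0, 0).

Timestamps are normalized to seconds internally; the declared native unit is
retained on the :class:`TrajectorySet` for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

_TIME_UNIT_SECONDS = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "min": 60.0, "minutes": 60.0}

DIALECTS = ("planar", "geographic", "displacement")


class TrajectoryError(ValueError):
    """Raised for malformed trajectory tables or inconsistent inputs."""


@dataclass
class Trajectory:
    """One animal's time-ordered track.

    ``t`` is in seconds, strictly increasing; ``xy`` is an (n, 2) array whose
    meaning depends on ``dialect`` ((x, y) or (lon, lat)); ``z`` is an optional
    height/depth column (sign convention declared by the caller).
    """

    animal_id: str
    t: np.ndarray
    xy: np.ndarray
    dialect: str = "planar"
    z: np.ndarray | None = None
    condition: str | None = None
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        if self.dialect not in DIALECTS:
            raise TrajectoryError(f"unknown dialect {self.dialect!r}")
        if self.t.ndim != 1 or len(self.t) < 2:
            raise TrajectoryError("a trajectory needs at least 2 samples")
        if self.xy.shape != (len(self.t), 2):
            raise TrajectoryError("xy must be (n, 2) aligned with t")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise TrajectoryError("timestamps and coordinates must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise TrajectoryError(f"timestamps not strictly increasing for {self.animal_id!r}")
        if self.dialect == "geographic":
            lon, lat = self.xy[:, 0], self.xy[:, 1]
            if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
                raise TrajectoryError("geographic coordinates out of range")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if len(self.truth_labels) != len(self.t):
                raise TrajectoryError("truth_labels must align with samples")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def native_interval(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TrajectorySet:
    """A cohort of trajectories sharing dialect and units."""

    trajectories: list[Trajectory]
    length_unit: str = "a.u."
    time_unit_native: str = "s"

    def __post_init__(self) -> None:
        if self.trajectories:
            dialects = {tr.dialect for tr in self.trajectories}
            if len(dialects) > 1:
                raise TrajectoryError(f"mixed dialects in one set: {sorted(dialects)}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def dialect(self) -> str:
        return self.trajectories[0].dialect if self.trajectories else "planar"

    def durations(self) -> np.ndarray:
        return np.array([tr.duration for tr in self.trajectories])

    def median_native_interval(self) -> float:
        return float(np.median([tr.native_interval for tr in self.trajectories]))


_DEFAULT_COLUMNS = {
    "planar": {"id": "id", "t": "t", "x": "x", "y": "y"},
    "geographic": {"id": "id", "t": "t", "x": "lon", "y": "lat"},
    "displacement": {"id": "id", "t": "t", "x": "dx", "y": "dy"},
}


def read_trajectory_table(
    path,
    dialect: str = "planar",
    columns: dict[str, str] | None = None,
    time_unit: str = "s",
    length_unit: str = "a.u.",
) -> TrajectorySet:
    """Read a delimited trajectory table (comma or tab, auto-detected).

    ``columns`` remaps the required header names; keys are ``id``, ``t``,
    ``x``, ``y`` and optionally ``z``, ``condition``, ``label``. One
    :class:`Trajectory` is produced per distinct animal id, rows sorted by
    time within an animal. Displacement increments are cumulatively summed to
    positions starting at (0, 0).
    """
    if dialect not in DIALECTS:
        raise TrajectoryError(f"unknown dialect {dialect!r}")
    colmap = dict(_DEFAULT_COLUMNS[dialect])
    if columns:
        colmap.update(columns)
    scale = _TIME_UNIT_SECONDS.get(time_unit)
    if scale is None:
        raise TrajectoryError(f"unknown time unit {time_unit!r}")

    df = pd.read_csv(path, sep=None, engine="python")
    for key in ("id", "t", "x", "y"):
        if colmap[key] not in df.columns:
            raise TrajectoryError(f"missing required column {colmap[key]!r}")
    for key in ("t", "x", "y"):
        col = pd.to_numeric(df[colmap[key]], errors="coerce")
        if col.isna().any():
            raise TrajectoryError(f"non-numeric value in column {colmap[key]!r}")
        df[colmap[key]] = col

    z_col = colmap.get("z") if colmap.get("z") in df.columns else None
    cond_col = colmap.get("condition") if colmap.get("condition") in df.columns else None
    label_col = colmap.get("label") if colmap.get("label") in df.columns else None

    trajectories: list[Trajectory] = []
    for animal_id, grp in df.groupby(colmap["id"], sort=True):
        grp = grp.sort_values(colmap["t"], kind="mergesort")
        t = grp[colmap["t"]].to_numpy(dtype=float) * scale
        if np.any(np.diff(t) == 0):
            raise TrajectoryError(f"duplicate timestamp for animal {animal_id!r}")
        xy = grp[[colmap["x"], colmap["y"]]].to_numpy(dtype=float)
        if dialect == "displacement":
            # Each row is the increment over the interval ending at its
            # timestamp: n rows -> n+1 positions, origin (0, 0) one native
            # interval before the first row.
            step = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
            t = np.concatenate([[t[0] - step], t])
            xy = np.vstack([[0.0, 0.0], np.cumsum(xy, axis=0)])
        z = grp[z_col].to_numpy(dtype=float) if z_col else None
        condition = str(grp[cond_col].iloc[0]) if cond_col else None
        labels = grp[label_col].to_numpy() if label_col else None
        if dialect == "displacement":
            if z is not None:
                z = np.concatenate([z[:1], z])
            if labels is not None:
                labels = np.concatenate([labels[:1], labels])
        trajectories.append(
            Trajectory(
                animal_id=str(animal_id),
                t=t,
                xy=xy,
                dialect="planar" if dialect == "displacement" else dialect,
                z=z,
                condition=condition,
                truth_labels=labels,
            )
        )
    return TrajectorySet(trajectories, length_unit=length_unit, time_unit_native=time_unit)


def interpolate_gaps(
    traj: Trajectory, target_interval: float, max_gap_factor: float = 60.0
) -> list[Trajectory]:
    """Resample a trajectory onto a uniform grid by linear interpolation.

    Returns a list of uniformly sampled segments: gaps wider than
    ``max_gap_factor * target_interval`` are not interpolated across; the
    trajectory is split there instead. No extrapolation beyond the first/last
    sample. Values at original grid-aligned sample times are preserved.
    """
    if target_interval <= 0:
        raise TrajectoryError("target_interval must be positive")
    max_gap = max_gap_factor * target_interval
    dt = np.diff(traj.t)
    breaks = np.flatnonzero(dt > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(traj.t)]])

    segments: list[Trajectory] = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        if b - a < 2:
            continue
        t = traj.t[a:b]
        n_steps = int(np.floor((t[-1] - t[0]) / target_interval + 1e-9))
        if n_steps < 1:
            continue
        grid = t[0] + target_interval * np.arange(n_steps + 1)
        xy = np.column_stack([np.interp(grid, t, traj.xy[a:b, j]) for j in range(2)])
        z = np.interp(grid, t, traj.z[a:b]) if traj.z is not None else None
        labels = None
        if traj.truth_labels is not None:
            idx = np.searchsorted(t, grid + 1e-9, side="right") - 1
            labels = traj.truth_labels[a:b][np.clip(idx, 0, b - a - 1)]
        suffix = "" if len(starts) == 1 else f"#{i}"
        segments.append(
            Trajectory(
                animal_id=traj.animal_id + suffix,
                t=grid,
                xy=xy,
                dialect=traj.dialect,
                z=z,
                condition=traj.condition,
                truth_labels=labels,
            )
        )
    if not segments:
        raise TrajectoryError("no segment long enough to resample")
    return segments


def resample_set(
    trajset: TrajectorySet, target_interval: float, max_gap_factor: float = 60.0
) -> TrajectorySet:
    """Apply :func:`interpolate_gaps` to every member of a set."""
    out: list[Trajectory] = []
    for tr in trajset:
        out.extend(interpolate_gaps(tr, target_interval, max_gap_factor))
    return TrajectorySet(out, length_unit=trajset.length_unit, time_unit_native=trajset.time_unit_native)


def haversine_distance(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters on a sphere of radius 6,371,000 m."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_azimuth(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing in degrees, clockwise from true north, in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    az = np.degrees(np.arctan2(x, y)) % 360.0
    # Convention: identical points have zero azimuth.
    both_zero = (np.asarray(x) == 0) & (np.asarray(y) == 0)
    return np.where(both_zero, 0.0, az)


def geo_step_metrics(p1: Sequence[float], p2: Sequence[float]) -> tuple[float, float]:
    """Distance (m) and azimuth (degrees in [0, 360)) between two (lon, lat) points."""
    d = float(haversine_distance(p1[0], p1[1], p2[0], p2[1]))
    az = float(initial_azimuth(p1[0], p1[1], p2[0], p2[1]))
    if d == 0.0:
        az = 0.0
    return d, az


def write_labeled_trajectory(trajset: TrajectorySet, labels: Iterable[np.ndarray], path) -> None:
    """Write per-frame cluster labels alongside coordinates as delimited text.

    ``labels`` holds one integer label array per trajectory, aligned 1:1 with
    that trajectory's frames. Round-trips through :func:`read_trajectory_table`
    (with a ``label`` column mapping) without loss.
    """
    labels = list(labels)
    if len(labels) != len(trajset.trajectories):
        raise TrajectoryError("one label array per trajectory is required")
    frames = []
    xcol = "lon" if trajset.dialect == "geographic" else "x"
    ycol = "lat" if trajset.dialect == "geographic" else "y"
    for tr, lab in zip(trajset, labels):
        lab = np.asarray(lab)
        if len(lab) != len(tr):
            raise TrajectoryError(
                f"label length {len(lab)} does not match {len(tr)} frames for {tr.animal_id!r}"
            )
        rec = {"id": tr.animal_id, "t": tr.t, xcol: tr.xy[:, 0], ycol: tr.xy[:, 1]}
        if tr.z is not None:
            rec["z"] = tr.z
        rec["label"] = lab
        frames.append(pd.DataFrame(rec))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
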