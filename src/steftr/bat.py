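"""Bat flight feature vectors around an obstacle chain array.

Each flight is a 3-D trajectory sampled at high speed (1/125 s frames by
default) through a vertical array of hanging chains. Eleven kinematic and
obstacle-relative features are evaluated at four analysis time points —
0.3, 0.2 and 0.1 s before, and while (t = 0) passing the array plane:

``V``        3-D flight speed (length/s)
``B_hori``   horizontal bearing, degrees clockwise from +y
``B_vert``   vertical bearing (climb angle), degrees
``R_obs``    distance to the nearest obstacle edge point
``B_obs``    horizontal bearing from the bat to that nearest point
``R_x``      longitudinal distance to the frontal array plane
``R_y``      lateral distance to the nearest chain
``dV, dB, ddB, dH``  per-frame differentials of V, B_hori, dB and height

The two cells that are degenerate at the passage instant (``R_x``, which is
zero there by construction, and ``B_obs``) are omitted, giving 42 feature
columns. Flights are additionally tagged with the early/middle/late term of
the session by flight order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import wrap_degrees
from .io import Trajectory

DEFAULT_FRAME_RATE = 125.0
TIME_OFFSETS = (-0.3, -0.2, -0.1, 0.0)
POINT_FEATURES = ("V", "B_hori", "B_vert", "R_obs", "B_obs", "R_x", "R_y", "dV", "dB", "ddB", "dH")
DEGENERATE_AT_PASSAGE = frozenset({"R_x", "B_obs"})


@dataclass(frozen=True)
class ObstacleArray:
    """Chain-array geometry: 3-D edge points of chains hanging in a plane.

    ``points`` is (k, 3); the frontal plane is x = mean chain x; chains are
    distinguished by their y positions.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.atleast_2d(np.asarray(self.points, dtype=float)))
        if self.points.shape[1] != 3:
            raise ValueError("obstacle points must be (k, 3)")

    @property
    def plane_x(self) -> float:
        return float(self.points[:, 0].mean())

    @property
    def chain_y(self) -> np.ndarray:
        return np.unique(self.points[:, 1])

    def nearest_distance_and_bearing(self, pos: np.ndarray) -> tuple[float, float]:
        d = np.linalg.norm(self.points - pos, axis=1)
        i = int(np.argmin(d))
        delta = self.points[i] - pos
        bearing = float(np.degrees(np.arctan2(delta[0], delta[1])) % 360.0)
        return float(d[i]), bearing


def feature_columns() -> list[str]:
    """The 42 feature column names of the default enumeration."""
    cols = []
    for feat in POINT_FEATURES:
        for off in TIME_OFFSETS:
            if off == 0.0 and feat in DEGENERATE_AT_PASSAGE:
                continue
            tag = "t0" if off == 0.0 else f"t{off:+.1f}s"
            cols.append(f"{feat}_{tag}")
    return cols


def _flight_series(traj: Trajectory, frame_rate: float) -> dict[str, np.ndarray]:
    if traj.z is None:
        raise ValueError("bat flights need a z (height) column")
    pos = np.column_stack([traj.xy, traj.z])
    steps = np.diff(pos, axis=0)
    horiz = np.hypot(steps[:, 0], steps[:, 1])
    v = np.linalg.norm(steps, axis=1) * frame_rate
    b_hori = np.degrees(np.arctan2(steps[:, 0], steps[:, 1])) % 360.0
    b_vert = np.degrees(np.arctan2(steps[:, 2], horiz))
    db = wrap_degrees(np.diff(b_hori))
    return {
        "V": v,
        "B_hori": b_hori,
        "B_vert": b_vert,
        "dV": np.diff(v),
        "dB": db,
        "ddB": np.diff(db),
        "dH": steps[:, 2],
    }


def _passage_index(traj: Trajectory, plane_x: float) -> int:
    x = traj.xy[:, 0]
    sign = np.sign(x - plane_x)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    if len(crossings) == 0:
        return int(np.argmin(np.abs(x - plane_x)))
    return int(crossings[0] + 1)


def bat_feature_vector(
    flights: list[Trajectory],
    obstacles: ObstacleArray,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> pd.DataFrame:
    """One row per flight with the 42-column obstacle-passage feature set.

    Flights shorter than 0.3 s before the passage get missing cells for the
    unreachable time points. A ``segment`` metadata column tags each flight
    with the early/middle/late tercile of its order in ``flights``.
    """
    n_flights = len(flights)
    rows = []
    for i, traj in enumerate(flights):
        series = _flight_series(traj, frame_rate)
        pos = np.column_stack([traj.xy, traj.z])
        k0 = _passage_index(traj, obstacles.plane_x)
        row: dict[str, float | str] = {"flight_id": traj.animal_id}
        tercile = int(3 * i / max(n_flights, 1))
        row["segment"] = ("early", "middle", "late")[min(tercile, 2)]
        for off in TIME_OFFSETS:
            k = k0 + int(round(off * frame_rate))
            tag = "t0" if off == 0.0 else f"t{off:+.1f}s"
            in_range = 0 <= k < len(traj)
            for feat in POINT_FEATURES:
                if off == 0.0 and feat in DEGENERATE_AT_PASSAGE:
                    continue
                name = f"{feat}_{tag}"
                if not in_range:
                    row[name] = np.nan
                    continue
                if feat == "R_obs":
                    d, _ = obstacles.nearest_distance_and_bearing(pos[k])
                    row[name] = d
                elif feat == "B_obs":
                    _, bearing = obstacles.nearest_distance_and_bearing(pos[k])
                    row[name] = bearing
                elif feat == "R_x":
                    row[name] = abs(pos[k, 0] - obstacles.plane_x)
                elif feat == "R_y":
                    row[name] = float(np.min(np.abs(obstacles.chain_y - pos[k, 1])))
                else:
                    arr = series[feat]
                    row[name] = float(arr[k]) if k < len(arr) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).reindex(columns=["flight_id", "segment"] + feature_columns())
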