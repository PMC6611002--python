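"""Worm-specific machinery: turns, run/pirouette classification and the
cluster-0 segment feature vector.

Nematode locomotion alternates between *runs* (long straight stretches) and
*pirouettes* (bouts of frequent reversals and sharp turns). A movement of
1 s with an angular change larger than 90 degrees counts as a turn; the
histogram of inter-turn intervals is well described by the sum of two
exponentials, and the interval at which the two exponentials intersect
(``t_crit``) separates within-pirouette intervals (short) from runs (long):

    t_crit = ln(a1 / a2) / (1/tau1 - 1/tau2).

Per cluster-0 segment, a configurable enumeration of summary features is
computed: the series features {V, dV, B, dB, C, dC} summarized by average
and median over the initiation / middle / termination / whole-segment
periods at time windows of 1-6 s, a windowed directedness block, the
weathervane index, and the durations of the segment and the following bout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .features import compute_primitives, time_differential, wrap_degrees
from .io import Trajectory
from .states import StateAnnotation

TURN_ANGLE_DEG = 90.0
DEFAULT_WINDOWS = (1, 2, 3, 4, 5, 6)
SERIES_FEATURES = ("V", "dV", "B", "dB", "C", "dC")
PERIODS = ("Ini", "Mid", "Ter", "All")
STATS = ("Ave", "Med")

RUN, PIROUETTE = 0, 1


# ---------------------------------------------------------------------------
# odor fields


class OdorField(Protocol):
    """Deterministic concentration field c(x, y, t) with a spatial gradient."""

    def concentration(self, xy: np.ndarray, t: np.ndarray | float) -> np.ndarray: ...

    def gradient(self, xy: np.ndarray, t: np.ndarray | float) -> np.ndarray: ...


@dataclass(frozen=True)
class LinearOdorField:
    """c = base + g . (x, y); a constant planar gradient."""

    gradient_vector: tuple[float, float] = (1.0, 0.0)
    base: float = 100.0

    def concentration(self, xy, t=0.0):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        g = np.asarray(self.gradient_vector)
        c = self.base + xy @ g
        return np.maximum(c, 0.0)

    def gradient(self, xy, t=0.0):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.broadcast_to(np.asarray(self.gradient_vector, dtype=float), xy.shape).copy()


@dataclass(frozen=True)
class GaussianOdorField:
    """A static 2-D Gaussian source: c = amplitude * exp(-|r - r0|^2 / (2 s^2))."""

    center: tuple[float, float] = (0.0, 0.0)
    sigma: float = 10.0
    amplitude: float = 100.0

    def concentration(self, xy, t=0.0):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = ((xy - np.asarray(self.center)) ** 2).sum(axis=1)
        return self.amplitude * np.exp(-d2 / (2 * self.sigma**2))

    def gradient(self, xy, t=0.0):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c = self.concentration(xy, t)
        return -(xy - np.asarray(self.center)) / self.sigma**2 * c[:, None]


# ---------------------------------------------------------------------------
# turns and the two-exponential interval model


def detect_turns(traj: Trajectory) -> np.ndarray:
    """Boolean per-frame turn flags: |wrapped bearing change| > 90 degrees.

    The trajectory is expected at 1-s frames; the change at frame k compares
    the step into frame k with the step out of it.
    """
    _, bearing = compute_primitives(traj, time_unit=traj.native_interval)
    db = time_differential(bearing, circular=True)
    turns = np.zeros(len(traj), dtype=bool)
    turns[1 : 1 + len(db)] = np.abs(db) > TURN_ANGLE_DEG
    return turns


def turn_intervals(traj: Trajectory) -> np.ndarray:
    """Durations (s) between consecutive turns of one trajectory."""
    turns = detect_turns(traj)
    times = traj.t[turns]
    return np.diff(times)


def intersection_time(a1: float, tau1: float, a2: float, tau2: float) -> float:
    """Where a1 exp(-t/tau1) and a2 exp(-t/tau2) intersect (closed form)."""
    if tau1 == tau2:
        raise ValueError("time constants must differ")
    return float(np.log(a1 / a2) / (1.0 / tau1 - 1.0 / tau2))


@dataclass
class RunPirouetteModel:
    """Two-exponential fit to the turn-interval histogram."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    crossing: bool

    def __post_init__(self) -> None:
        if self.tau1 > self.tau2:  # store fast component first
            self.a1, self.a2 = self.a2, self.a1
            self.tau1, self.tau2 = self.tau2, self.tau1

    @property
    def t_crit(self) -> float | None:
        if not self.crossing:
            return None
        return intersection_time(self.a1, self.tau1, self.a2, self.tau2)

    def density(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-t / self.tau1) + self.a2 * np.exp(-t / self.tau2)


def fit_turn_interval_model(
    intervals,
    n_bins: int = 24,
    n_starts: int = 10,
    seed: int = 1,
) -> RunPirouetteModel:
    """Fit a1 exp(-t/tau1) + a2 exp(-t/tau2) to the interval histogram.

    The histogram uses log-spaced bins and the residuals are taken on
    log-density (two-exponential fits are ill-conditioned on the raw scale);
    parameters are optimized in log space (positivity by construction) with
    multi-start least squares. A fit whose fast component does not dominate
    at t=0 (a1 <= a2) cannot cross and is flagged.
    """
    intervals = np.asarray(intervals, dtype=float)
    intervals = intervals[np.isfinite(intervals) & (intervals > 0)]
    if len(intervals) < 50:
        raise ValueError("need at least 50 intervals")
    lo, hi = intervals.min(), intervals.max()
    edges = np.geomspace(max(lo, 1e-3), hi * (1 + 1e-9), n_bins + 1)
    counts, edges = np.histogram(intervals, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (widths * len(intervals))
    keep = counts > 0
    x, y = centers[keep], np.log(dens[keep])
    # log-density residuals have variance ~ 1/count (Poisson), so weight by
    # sqrt(count) to keep sparse tail bins from dominating the fit
    w = np.sqrt(counts[keep])
    if keep.sum() < 4:
        raise ValueError("too few occupied histogram bins")

    def resid(logp):
        a1, t1, a2, t2 = np.exp(logp)
        model = a1 * np.exp(-x / t1) + a2 * np.exp(-x / t2)
        return w * (np.log(np.maximum(model, 1e-300)) - y)

    rng = np.random.default_rng(seed)
    scale = float(np.mean(intervals))
    best = None
    for _ in range(n_starts):
        t1 = scale * rng.uniform(0.05, 0.8)
        t2 = scale * rng.uniform(1.0, 8.0)
        a1 = np.exp(y.max()) * rng.uniform(0.5, 2.0)
        a2 = a1 * rng.uniform(0.01, 0.5)
        p0 = np.log([a1, t1, a2, t2])
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("two-exponential fit failed from all starts")
    a1, t1, a2, t2 = np.exp(best.x)
    if t1 > t2:
        a1, a2, t1, t2 = a2, a1, t2, t1
    crossing = a1 > a2
    return RunPirouetteModel(a1, t1, a2, t2, crossing)


def classify_run_pirouette(traj: Trajectory, t_crit: float) -> np.ndarray:
    """Per-frame run (0) / pirouette (1) labels from turn timing.

    Inter-turn intervals no longer than ``t_crit`` are pirouette (including
    their bounding turn frames); everything else, including a trajectory with
    no turns, is run.
    """
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    labels = np.full(len(traj), RUN, dtype=int)
    turns = np.flatnonzero(detect_turns(traj))
    for i in range(len(turns) - 1):
        a, b = turns[i], turns[i + 1]
        if traj.t[b] - traj.t[a] <= t_crit:
            labels[a : b + 1] = PIROUETTE
    return labels


# ---------------------------------------------------------------------------
# segment geometry


def directedness(xy) -> float:
    """Net start-to-end displacement over summed step lengths, in [0, 1]."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least 2 points")
    steps = np.diff(xy, axis=0)
    path = np.hypot(steps[:, 0], steps[:, 1]).sum()
    if path == 0:
        raise ValueError("zero path length")
    net = float(np.hypot(*(xy[-1] - xy[0])))
    return float(net / path)


def weathervane(xy, field: OdorField, t=None) -> float:
    """Mean signed curving rate (deg per unit path length) toward the gradient.

    Positive when the path bends toward the local up-gradient direction,
    negative when it bends away; points with an undefined (zero) gradient are
    skipped.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 points")
    steps = np.diff(xy, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    bearing = np.degrees(np.arctan2(steps[:, 0], steps[:, 1])) % 360.0
    db = wrap_degrees(np.diff(bearing))
    if t is None:
        t = np.zeros(len(xy))
    grad = np.atleast_2d(field.gradient(xy[1:-1], np.asarray(t)[1:-1]))
    grad_bearing = np.degrees(np.arctan2(grad[:, 0], grad[:, 1])) % 360.0
    eta = wrap_degrees(grad_bearing - bearing[:-1])
    ds = (lengths[:-1] + lengths[1:]) / 2.0
    ok = (np.hypot(grad[:, 0], grad[:, 1]) > 0) & (ds > 0)
    if not ok.any():
        raise ValueError("gradient undefined along the whole segment")
    contrib = (db[ok] / ds[ok]) * np.sign(eta[ok])
    return float(np.mean(contrib))


def odor_exposure(xy, field: OdorField, t=None) -> tuple[np.ndarray, np.ndarray]:
    """Concentration series along a path and its per-frame change."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if t is None:
        t = np.zeros(len(xy))
    c = np.asarray(field.concentration(xy, np.asarray(t)), dtype=float).reshape(-1)
    return c, np.diff(c)


# ---------------------------------------------------------------------------
# the cluster-0 segment feature vector


@dataclass(frozen=True)
class WormFeatureConfig:
    """Enumeration scheme for the per-segment feature vector.

    The default scheme yields 333 columns: 6 series features x 2 stats x 4
    periods x 6 windows (288), a directedness block (2 stats x 3 periods x 6
    windows + 1 whole-segment scalar per window = 42), and WV, Clst0Dur,
    Clst1Dur (3).
    """

    windows: tuple[int, ...] = DEFAULT_WINDOWS
    series_features: tuple[str, ...] = SERIES_FEATURES
    stats: tuple[str, ...] = STATS
    periods: tuple[str, ...] = PERIODS
    include_weathervane: bool = True
    include_durations: bool = True

    def column_names(self) -> list[str]:
        cols = [
            f"{feat}_{stat}_{period}_w{w}"
            for feat in self.series_features
            for stat in self.stats
            for period in self.periods
            for w in self.windows
        ]
        cols += [
            f"Dir_{stat}_{period}_w{w}"
            for stat in self.stats
            for period in ("Ini", "Mid", "Ter")
            for w in self.windows
        ]
        cols += [f"Dir_All_w{w}" for w in self.windows]
        if self.include_weathervane:
            cols.append("WV")
        if self.include_durations:
            cols += ["Clst0Dur", "Clst1Dur"]
        return cols


def _moving_average(series: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(series) < w:
        return series
    kernel = np.ones(w) / w
    return np.convolve(series, kernel, mode="valid")


def _period_slice(n: int, w: int, period: str) -> slice | None:
    if period == "All":
        return slice(0, n)
    if n < w:
        return None
    if period == "Ini":
        return slice(0, w)
    if period == "Ter":
        return slice(n - w, n)
    start = max(0, (n - w) // 2)
    return slice(start, start + w)


def _summarize(series: np.ndarray, stat: str) -> float:
    if len(series) == 0 or not np.any(np.isfinite(series)):
        return np.nan
    if stat == "Ave":
        return float(np.nanmean(series))
    return float(np.nanmedian(series))


def _trailing_directedness(xy: np.ndarray, w: int) -> np.ndarray:
    """Per-frame directedness of the trailing w-step path (NaN where undefined)."""
    n = len(xy)
    out = np.full(n, np.nan)
    steps = np.diff(xy, axis=0)
    seglen = np.hypot(steps[:, 0], steps[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    for k in range(w, n):
        path = cum[k] - cum[k - w]
        if path > 0:
            out[k] = np.hypot(*(xy[k] - xy[k - w])) / path
    return out


def _segment_runs(labels: np.ndarray, cluster_id: int) -> list[tuple[int, int]]:
    mask = np.asarray(labels) == cluster_id
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    ends = idx[np.concatenate([np.diff(idx) > 1, [True]])]
    return list(zip(starts, ends + 1))


def worm_feature_vector(
    annotation: StateAnnotation,
    odor_field: OdorField | None = None,
    config: WormFeatureConfig | None = None,
    cluster_id: int = 0,
) -> pd.DataFrame:
    """Per cluster-0 segment feature table for the annotated cohort.

    One row per maximal run of ``cluster_id``; columns follow
    :meth:`WormFeatureConfig.column_names` plus ``animal_id`` and, when the
    trajectories carry one, ``condition``. Cells whose period is shorter than
    the requested window are missing (NaN).
    """
    if annotation.trajset is None:
        raise ValueError("annotation does not carry its trajectories")
    config = config or WormFeatureConfig()
    if odor_field is None:
        config = WormFeatureConfig(
            windows=config.windows,
            series_features=tuple(f for f in config.series_features if f not in ("C", "dC")),
            stats=config.stats,
            periods=config.periods,
            include_weathervane=False,
            include_durations=config.include_durations,
        )
    time_unit = annotation.params.time_unit
    rows = []
    for tr, labels in zip(annotation.trajset, annotation.labels):
        v, b = compute_primitives(tr, time_unit)
        dv = time_differential(v)
        db = time_differential(b, circular=True)
        series_full: dict[str, np.ndarray] = {"V": v, "dV": dv, "B": b, "dB": db}
        if odor_field is not None:
            c, dc = odor_exposure(tr.xy, odor_field, tr.t)
            series_full["C"] = c
            series_full["dC"] = dc
        runs = _segment_runs(labels, cluster_id)
        for seg_i, (s, e) in enumerate(runs):
            row: dict[str, float | str] = {"animal_id": tr.animal_id}
            if tr.condition is not None:
                row["condition"] = tr.condition
            n = e - s
            xy = tr.xy[s:e]
            for feat in config.series_features:
                full = series_full[feat]
                seg = full[s : min(e, len(full))]
                for w in config.windows:
                    wf = max(1, round(w / time_unit))
                    smoothed = _moving_average(seg, wf)
                    m = len(smoothed)
                    for period in config.periods:
                        sl = _period_slice(m, wf, period)
                        for stat in config.stats:
                            name = f"{feat}_{stat}_{period}_w{w}"
                            row[name] = np.nan if sl is None or m == 0 else _summarize(smoothed[sl], stat)
            for w in config.windows:
                wf = max(1, round(w / time_unit))
                dir_series = _trailing_directedness(xy, wf) if n > wf else np.full(n, np.nan)
                m = len(dir_series)
                for period in ("Ini", "Mid", "Ter"):
                    sl = _period_slice(m, wf, period)
                    for stat in config.stats:
                        name = f"Dir_{stat}_{period}_w{w}"
                        row[name] = np.nan if sl is None else _summarize(dir_series[sl], stat)
                try:
                    sm_xy = np.column_stack(
                        [_moving_average(xy[:, 0], wf), _moving_average(xy[:, 1], wf)]
                    )
                    row[f"Dir_All_w{w}"] = directedness(sm_xy) if len(sm_xy) >= 2 else np.nan
                except ValueError:
                    row[f"Dir_All_w{w}"] = np.nan
            if config.include_weathervane and odor_field is not None:
                try:
                    row["WV"] = weathervane(xy, odor_field, tr.t[s:e]) if n >= 3 else np.nan
                except ValueError:
                    row["WV"] = np.nan
            if config.include_durations:
                row["Clst0Dur"] = n * time_unit
                nxt = np.nan
                if e < len(labels):
                    j = e
                    while j < len(labels) and labels[j] != cluster_id:
                        j += 1
                    nxt = (j - e) * time_unit
                row["Clst1Dur"] = nxt
            rows.append(row)
    meta = ["animal_id"] + (["condition"] if rows and "condition" in rows[0] else [])
    frame = pd.DataFrame(rows)
    ordered = meta + [c for c in config.column_names() if c in frame.columns]
    return frame.reindex(columns=ordered)
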