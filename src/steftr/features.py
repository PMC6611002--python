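"""The eight basic behavioral features and their histograms.

From a uniformly resampled trajectory, two primitives are computed per time
frame: velocity ``V`` (step distance per time unit) and bearing ``B`` (heading
of the step, degrees clockwise from +y / true north, in [0, 360)). Their
per-frame differentials ``dV`` and ``dB`` (the latter wrapped into
(-180, 180]) complete the four raw streams. Each stream is summarized by a
centered moving average (``Ave``) and moving variance (``Var``) over a time
window, giving eight features: V_Ave, V_Var, dV_Ave, dV_Var, B_Ave, B_Var,
dB_Ave, dB_Var.

The time frame and window default to ~1/1000 and ~1/100 of the median
recording duration across animals, snapped to a 1-2-5 grid; species presets
override the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory, TrajectorySet, haversine_distance, initial_azimuth
from .presets import PRESETS

FEATURE_ORDER = ("V_Ave", "V_Var", "dV_Ave", "dV_Var", "B_Ave", "B_Var", "dB_Ave", "dB_Var")

CIRCULAR_KINDS = frozenset({"B_Ave", "B_Var"})


@dataclass(frozen=True)
class TimeParameters:
    """Time frame length and moving-average span, both in seconds.

    ``window=None`` disables smoothing (raw streams are used, as for
    high-rate recordings where every frame matters).
    """

    time_unit: float
    window: float | None
    source: str = "auto"

    def window_frames(self) -> int | None:
        """Window span as an odd number of frames (centered window)."""
        if self.window is None:
            return None
        w = max(1, round(self.window / self.time_unit))
        return w if w % 2 == 1 else w + 1


def _snap_125(value: float) -> float:
    """Snap to the nearest value on the 1-2-5 grid (closest in log ratio)."""
    if value <= 0:
        raise ValueError("cannot snap a non-positive duration")
    exponent = np.floor(np.log10(value))
    candidates = np.array([1.0, 2.0, 5.0, 10.0]) * 10.0**exponent
    candidates = np.concatenate([[0.5 * 10.0**exponent], candidates])
    return float(candidates[np.argmin(np.abs(np.log(candidates / value)))])


def auto_time_parameters(
    recording_durations, native_interval: float, preset: str | None = None
) -> TimeParameters:
    """Choose the time unit and moving-average window for a cohort.

    The rule of thumb: unit = median duration / 1000 and window = median
    duration / 100, each snapped to the 1-2-5 grid and floored at the native
    sampling interval. A species preset overrides the rule entirely.
    """
    if preset is not None:
        p = PRESETS[preset]
        return TimeParameters(p.time_unit, p.window, source="preset")
    durations = np.asarray(list(recording_durations), dtype=float)
    if durations.size == 0:
        raise ValueError("at least one recording duration is required")
    median = float(np.median(durations))
    unit = max(_snap_125(median / 1000.0), native_interval)
    window = max(_snap_125(median / 100.0), native_interval)
    if window < unit:
        window = unit
    return TimeParameters(unit, window, source="auto")


def wrap_degrees(angle):
    """Wrap angles into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(-(a + 180.0) % 360.0 - 180.0)
    return wrapped


def compute_primitives(traj: Trajectory, time_unit: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame velocity and bearing of a uniformly resampled trajectory.

    ``V[k]`` is the step length between frames k and k+1 expressed per time
    unit; ``B[k]`` is the heading of that step in [0, 360). Zero-displacement
    frames carry the previous bearing forward (the first moving frame defines
    the bearing for any leading stationary frames).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    if time_unit is None:
        time_unit = traj.native_interval
    if traj.dialect == "geographic":
        lon, lat = traj.xy[:, 0], traj.xy[:, 1]
        dist = haversine_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])
        bearing = initial_azimuth(lon[:-1], lat[:-1], lon[1:], lat[1:])
    else:
        steps = np.diff(traj.xy, axis=0)
        dist = np.hypot(steps[:, 0], steps[:, 1])
        bearing = np.degrees(np.arctan2(steps[:, 0], steps[:, 1])) % 360.0
    frame_dt = np.diff(traj.t)
    v = dist / frame_dt * time_unit

    moving = dist > 0
    if not np.any(moving):
        bearing = np.zeros_like(bearing)
    else:
        # forward-fill bearings over stationary frames; back-fill the head
        idx = np.where(moving, np.arange(len(bearing)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(moving)
        idx[idx < 0] = first
        bearing = bearing[idx]
    return v, bearing


def time_differential(series, circular: bool = False) -> np.ndarray:
    """First difference ``X[k+1] - X[k]``; wrapped into (-180, 180] if circular."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("series too short to differentiate")
    d = np.diff(series)
    return wrap_degrees(d) if circular else d


def _sliding_view(series: np.ndarray, window: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(series, window)


def sliding_stats(series, window: int | None, circular: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean and variance, same length as input, NaN at edges.

    For circular series the mean is the circular mean mapped into [0, 360)
    and the variance is the mean squared wrapped deviation from it (deg^2).
    ``window=None`` returns the raw series with zero variance.
    """
    series = np.asarray(series, dtype=float)
    if window is None:
        return series.copy(), np.zeros_like(series)
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be an odd number of frames")
    if window > len(series):
        raise ValueError("window longer than series")
    half = window // 2
    view = _sliding_view(series, window)
    if circular:
        rad = np.radians(view)
        s, c = np.sin(rad).mean(axis=1), np.cos(rad).mean(axis=1)
        mean = np.degrees(np.arctan2(s, c)) % 360.0
        dev = wrap_degrees(view - mean[:, None])
        var = np.mean(dev**2, axis=1)
    else:
        mean = view.mean(axis=1)
        var = view.var(axis=1)
    ave = np.full_like(series, np.nan)
    v = np.full_like(series, np.nan)
    ave[half : len(series) - half] = mean
    v[half : len(series) - half] = var
    return ave, v


def feature_streams(
    traj: Trajectory, params: TimeParameters, circular_bearing: bool = True
) -> dict[str, np.ndarray]:
    """All eight feature series for one resampled trajectory.

    Every returned array has one value per trajectory frame; positions where
    a feature is undefined (differentiation and window losses at the edges)
    hold NaN, keeping frame alignment trivial.
    """
    m = len(traj)
    w = params.window_frames()
    v, b = compute_primitives(traj, params.time_unit)
    dv = time_differential(v)
    db = time_differential(b, circular=True)

    def padded(arr: np.ndarray, offset: int) -> np.ndarray:
        out = np.full(m, np.nan)
        out[offset : offset + len(arr)] = arr
        return out

    streams: dict[str, np.ndarray] = {}
    for name, arr, offset, circ in (
        ("V", v, 0, False),
        ("dV", dv, 0, False),
        ("B", b, 0, circular_bearing),
        ("dB", db, 0, False),
    ):
        if w is not None and w > len(arr):
            ave = np.full(len(arr), np.nan)
            var = np.full(len(arr), np.nan)
        else:
            ave, var = sliding_stats(arr, w, circular=circ)
        streams[f"{name}_Ave"] = padded(ave, offset)
        streams[f"{name}_Var"] = padded(var, offset)
    return streams


@dataclass
class FeatureHistogram:
    """Pooled histogram of one basic feature across a cohort."""

    feature_kind: str
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    usable: bool = True

    @property
    def n(self) -> int:
        return len(self.values)


def _degenerate(values: np.ndarray, ref_scale: float) -> bool:
    if values.size == 0:
        return True
    span = float(np.ptp(values))
    # a spread at floating-point noise level of the parent quantity is no spread
    return span == 0.0 or span <= 1e-9 * max(ref_scale, 1e-300)


def _histogram(kind: str, values: np.ndarray, ref_scale: float = 0.0, min_bins: int = 30) -> FeatureHistogram:
    values = values[np.isfinite(values)]
    if _degenerate(values, ref_scale):
        edges = np.array([values.min() - 0.5, values.max() + 0.5]) if values.size else np.array([0.0, 1.0])
        counts, _ = np.histogram(values, bins=edges)
        return FeatureHistogram(kind, values, edges, counts, usable=False)
    edges = np.histogram_bin_edges(values, bins="fd")
    if len(edges) - 1 < min_bins:
        edges = np.histogram_bin_edges(values, bins=min_bins)
    counts, edges = np.histogram(values, bins=edges)
    return FeatureHistogram(kind, values, edges, counts, usable=True)


def build_histograms(
    trajset: TrajectorySet,
    params: TimeParameters,
    circular_bearing: bool = True,
    min_bins: int = 30,
) -> dict[str, FeatureHistogram]:
    """The eight pooled feature histograms for a cohort.

    Binning uses the Freedman-Diaconis rule floored at ``min_bins`` bins;
    degenerate (constant) features are flagged unusable.
    """
    if len(trajset) == 0:
        raise ValueError("empty trajectory set")
    pooled: dict[str, list[np.ndarray]] = {k: [] for k in FEATURE_ORDER}
    for tr in trajset:
        streams = feature_streams(tr, params, circular_bearing=circular_bearing)
        for kind in FEATURE_ORDER:
            pooled[kind].append(streams[kind])
    values = {kind: np.concatenate(pooled[kind]) for kind in FEATURE_ORDER}
    v_pool = values["V_Ave"][np.isfinite(values["V_Ave"])]
    v_scale = float(np.max(np.abs(v_pool))) if v_pool.size else 1.0
    ref = {
        "V_Ave": v_scale,
        "dV_Ave": v_scale,
        "V_Var": v_scale**2,
        "dV_Var": v_scale**2,
        "B_Ave": 360.0,
        "dB_Ave": 360.0,
        "B_Var": 360.0**2,
        "dB_Var": 360.0**2,
    }
    return {
        kind: _histogram(kind, values[kind], ref_scale=ref[kind], min_bins=min_bins)
        for kind in FEATURE_ORDER
    }
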