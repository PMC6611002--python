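"""End-to-end behavioral-state estimation.

Pipeline: resample trajectories to the time unit -> compute the eight basic
feature streams -> pool each into a histogram -> for each histogram select
the cluster number by cross-validated likelihood, fit the mixture and score
it with the separation index -> keep the best-scoring feature with at least
two clusters -> assign each frame the maximum-posterior component of that
feature -> smooth labels with a sliding majority vote -> optionally extend
cluster 0 by half the window (compensates the moving-average smearing of
sudden feature changes at state boundaries).

Cluster ids are sorted by component mean, so "cluster 0" is always the
component with the smallest mean of the selected feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    FEATURE_ORDER,
    FeatureHistogram,
    TimeParameters,
    auto_time_parameters,
    build_histograms,
    feature_streams,
)
from .io import TrajectorySet, resample_set
from .mixtures import (
    CV_SUBSAMPLE,
    HistogramScore,
    MixtureFitError,
    MixtureModel,
    count_local_maxima,
    fit_gmm_em,
    refine_fit,
    select_cluster_number,
)
from .presets import PRESETS

DEFAULT_MAX_CLUSTERS = 5
SELECTION_SUBSAMPLE = 20_000
KDE_SUBSAMPLE = 10_000


@dataclass
class EstimateConfig:
    """Knobs for :func:`estimate_states`.

    ``extend`` grows cluster-0 runs by half the window to undo the
    moving-average smearing of state boundaries: ``"auto"`` (when a
    variance-type feature was selected), an explicit cluster id, or ``None``
    (default — the correction assumes state bouts much longer than the
    window and erases genuine short bouts otherwise). ``include_arena_bearing``
    admits the absolute-heading average (B_Ave) into feature selection;
    ``None`` means "only for geographic cohorts". ``selection_subsample``
    caps the number of pooled values used for model selection and fitting
    (labels are always assigned to every frame).
    """

    preset: str | None = None
    time_unit: float | None = None
    window: float | None = None
    max_clusters: int | None = None
    seed: int = 1
    circular_bearing: bool = True
    extend: str | int | None = None
    max_gap_factor: float = 60.0
    selection_subsample: int | None = SELECTION_SUBSAMPLE
    include_arena_bearing: bool | None = None
    merge_clusters: dict[int, int] | None = None


class NoStructureError(RuntimeError):
    """No feature histogram supported two or more separated clusters."""

    def __init__(self, scores: list[HistogramScore]):
        super().__init__("no basic feature produced two or more separated clusters")
        self.scores = scores


@dataclass
class StateAnnotation:
    """Per-frame cluster labels mapped back onto the resampled trajectories."""

    labels: list[np.ndarray]
    feature_kind: str | None
    model: MixtureModel | None
    params: TimeParameters
    scores: list[HistogramScore] = field(default_factory=list)
    trajset: TrajectorySet | None = None
    structure_found: bool = True

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate(self.labels)

    def pooled_truth(self) -> np.ndarray | None:
        if self.trajset is None:
            return None
        truths = [tr.truth_labels for tr in self.trajset]
        if any(t is None for t in truths):
            return None
        return np.concatenate(truths)


def smooth_labels(labels, window: int) -> np.ndarray:
    """Sliding majority vote over integer labels (centered window).

    Ties are resolved in favor of the incumbent (center) label; if the center
    label is not among the tied winners, the smallest tied label wins. Edges
    use the truncated window. Removes label runs shorter than roughly half
    the window.
    """
    labels = np.asarray(labels)
    if window is None or window <= 1:
        return labels.copy()
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = len(labels)
    half = window // 2
    uniq, inv = np.unique(labels, return_inverse=True)
    out = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts = np.bincount(inv[lo:hi], minlength=len(uniq))
        winners = np.flatnonzero(counts == counts.max())
        if inv[i] in winners:
            out[i] = labels[i]
        else:
            out[i] = uniq[winners[0]]
    return out


def extend_cluster_bounds(labels, cluster_id: int, half_window: int) -> np.ndarray:
    """Grow every maximal run of ``cluster_id`` by ``half_window`` frames per side.

    Extensions overwrite neighboring labels; runs whose extensions meet are
    merged into one.
    """
    labels = np.asarray(labels).copy()
    if half_window <= 0:
        return labels
    mask = labels == cluster_id
    if not mask.any():
        return labels
    idx = np.flatnonzero(mask)
    starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    ends = idx[np.concatenate([np.diff(idx) > 1, [True]])]
    for s, e in zip(starts, ends):
        labels[max(0, s - half_window) : min(len(labels), e + half_window + 1)] = cluster_id
    return labels


def _subsample(values: np.ndarray, cap: int | None, seed: int) -> np.ndarray:
    if cap is None or len(values) <= cap:
        return values
    rng = np.random.default_rng(seed)
    return rng.choice(values, size=cap, replace=False)


def score_histogram(
    hist: FeatureHistogram,
    max_clusters: int,
    seed: int = 1,
    subsample: int | None = SELECTION_SUBSAMPLE,
) -> tuple[HistogramScore, MixtureModel]:
    """Select N, fit the mixture and compute the separation score for one histogram.

    The multi-restart search runs on a small seeded subsample; the winning
    start is then refined to convergence on the full (capped) value pool.
    """
    values = _subsample(hist.values, subsample, seed)
    n = select_cluster_number(values, max_clusters, seed=seed)
    if n > 1 and len(values) > 2 * CV_SUBSAMPLE:
        coarse = fit_gmm_em(_subsample(values, CV_SUBSAMPLE, seed), n, seed=seed)
        model = refine_fit(values, coarse)
    else:
        model = fit_gmm_em(values, n, seed=seed)
    mx = count_local_maxima(hist.values, max_values=KDE_SUBSAMPLE, seed=seed)
    return HistogramScore.compute(hist.feature_kind, model, mx), model


def location_separated(model: MixtureModel, tolerance: float = 1.0) -> bool:
    """Whether adjacent components are actually separated in location.

    A mixture whose adjacent components share their mean (a scale mixture:
    one narrow and one broad component stacked concentrically) models heavy
    tails rather than distinct states, even though its weighted overlap can
    be small. Adjacent (mean-sorted) components must differ in mean by at
    least ``tolerance`` times the smaller of the two sigmas.
    """
    if model.n_components < 2:
        return True
    gaps = np.diff(model.means)
    min_sds = np.minimum(model.sds[:-1], model.sds[1:])
    return bool(np.all(gaps >= tolerance * min_sds))


def two_way_grouping(model: MixtureModel) -> dict[int, int]:
    """Merge mixture components into two groups at the widest separation.

    Adjacent (mean-sorted) components are split where the gap between their
    means, scaled by the geometric mean of their sigmas, is largest —
    generalizing the manual "cluster 0 vs clusters 1..k" grouping used when
    a two-state reading (e.g. run vs pirouette) is wanted. Components below
    the split map to group 0, the rest to group 1.
    """
    if model.n_components < 2:
        return {0: 0}
    gaps = np.diff(model.means) / np.sqrt(model.sds[:-1] * model.sds[1:])
    cut = int(np.argmax(gaps)) + 1
    return {i: (0 if i < cut else 1) for i in range(model.n_components)}


def select_best_feature(
    histograms: dict[str, FeatureHistogram],
    max_clusters: int,
    seed: int = 1,
    subsample: int | None = SELECTION_SUBSAMPLE,
    include_arena_bearing: bool = False,
    concentric_tolerance: float = 1.0,
) -> tuple[str | None, MixtureModel | None, list[HistogramScore]]:
    """Score all usable histograms; return the best multi-cluster feature.

    All eight histograms are scored for the report, but not all compete:

    * histograms whose selected N is 1 cannot represent separated states;
    * histograms failing :func:`location_separated` (concentric components)
      likewise represent no locational structure;
    * the absolute-bearing average (``B_Ave``) is the one basic feature that
      is not invariant under rotation of the arena — its clusters encode
      which way each animal happened to head, not what it was doing — so it
      competes only when the cohort has a meaningful absolute frame
      (``include_arena_bearing=True``, e.g. compass bearings of migrating
      animals).

    Ties break by larger (1 - Ov), then by the fixed feature order. Returns
    ``(None, None, scores)`` when nothing competes.
    """
    scores: list[HistogramScore] = []
    models: dict[str, MixtureModel] = {}
    for kind in FEATURE_ORDER:
        hist = histograms.get(kind)
        if hist is None or not hist.usable:
            continue
        try:
            score, model = score_histogram(hist, max_clusters, seed=seed, subsample=subsample)
        except (MixtureFitError, ValueError):
            continue
        scores.append(score)
        models[kind] = model
    candidates = [
        sc
        for sc in scores
        if sc.n_components >= 2
        and location_separated(models[sc.feature_kind], concentric_tolerance)
        and (include_arena_bearing or sc.feature_kind != "B_Ave")
    ]
    if not candidates:
        return None, None, scores
    order = {k: i for i, k in enumerate(FEATURE_ORDER)}
    best = max(
        candidates,
        key=lambda sc: (sc.separation, 1.0 - sc.overlap, -order[sc.feature_kind]),
    )
    return best.feature_kind, models[best.feature_kind], scores


def _labels_for_stream(stream: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Per-frame maximum-posterior labels; NaN frames take the nearest finite label."""
    labels = np.full(len(stream), -1, dtype=int)
    finite = np.isfinite(stream)
    if not finite.any():
        return np.zeros(len(stream), dtype=int)
    labels[finite] = model.assign(stream[finite])
    idx = np.where(finite, np.arange(len(stream)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(finite)
    idx[idx < 0] = first
    return labels[idx]


def estimate_states(trajset: TrajectorySet, config: EstimateConfig | None = None) -> StateAnnotation:
    """Run the full state-estimation pipeline on a cohort of trajectories.

    Deterministic given ``config.seed``. Raises :class:`NoStructureError`
    (carrying all histogram scores) when no basic feature supports two or
    more separated clusters.
    """
    config = config or EstimateConfig()
    native = trajset.median_native_interval()
    if config.time_unit is not None:
        params = TimeParameters(config.time_unit, config.window, source="user")
    else:
        params = auto_time_parameters(trajset.durations(), native, preset=config.preset)
    max_clusters = config.max_clusters
    if max_clusters is None:
        max_clusters = PRESETS[config.preset].max_clusters if config.preset else DEFAULT_MAX_CLUSTERS

    resampled = resample_set(trajset, params.time_unit, config.max_gap_factor)
    histograms = build_histograms(resampled, params, circular_bearing=config.circular_bearing)
    arena_bearing = config.include_arena_bearing
    if arena_bearing is None:
        arena_bearing = trajset.dialect == "geographic"
    kind, model, scores = select_best_feature(
        histograms,
        max_clusters,
        seed=config.seed,
        subsample=config.selection_subsample,
        include_arena_bearing=arena_bearing,
    )
    if kind is None:
        raise NoStructureError(scores)

    w = params.window_frames()
    half = (w // 2) if w else 0
    extend_id: int | None = None
    if config.extend == "auto":
        extend_id = 0 if kind.endswith("_Var") and w else None
    elif isinstance(config.extend, int):
        extend_id = config.extend

    labels: list[np.ndarray] = []
    for tr in resampled:
        stream = feature_streams(tr, params, circular_bearing=config.circular_bearing)[kind]
        lab = _labels_for_stream(stream, model)
        if w:
            lab = smooth_labels(lab, w)
        if extend_id is not None and half:
            lab = extend_cluster_bounds(lab, extend_id, half)
        if config.merge_clusters:
            lab = np.array([config.merge_clusters.get(int(v), int(v)) for v in lab])
        labels.append(lab)
    return StateAnnotation(
        labels=labels,
        feature_kind=kind,
        model=model,
        params=params,
        scores=scores,
        trajset=resampled,
    )
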