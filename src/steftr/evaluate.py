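"""Agreement between estimated clusters and reference behavioral states.

The matching matrix summarizes a binary frame-by-frame comparison:

    sensitivity = TP / (TP + FN)        false positive rate = FP / (FP + TN)
    specificity = TN / (TN + FP)        false negative rate = FN / (FN + TP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

Counts are computed per frame and, separately, per event (a contiguous run
of the positive class; a predicted event matches a reference event when
their temporal overlap covers at least half of the reference event).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MatchingMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    @property
    def false_negative_rate(self) -> float:
        return self.fn / (self.fn + self.tp) if self.fn + self.tp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def matching_matrix(pred_binary, truth_binary) -> MatchingMatrix:
    """Frame-level confusion counts of two aligned binary sequences."""
    pred = np.asarray(pred_binary, dtype=bool)
    truth = np.asarray(truth_binary, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same length")
    return MatchingMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _events(binary: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(binary)
    if len(idx) == 0:
        return []
    starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    ends = idx[np.concatenate([np.diff(idx) > 1, [True]])]
    return list(zip(starts, ends + 1))


def event_counts(pred_binary, truth_binary, overlap: float = 0.5) -> dict[str, int]:
    """Event-level tally: reference events matched / missed, spurious predictions.

    A reference event is *matched* when predicted-positive frames cover at
    least ``overlap`` of it; a predicted event with no reference frames
    covering at least ``overlap`` of it is *spurious*.
    """
    pred = np.asarray(pred_binary, dtype=bool)
    truth = np.asarray(truth_binary, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same length")
    matched = missed = 0
    for s, e in _events(truth):
        if pred[s:e].sum() >= overlap * (e - s):
            matched += 1
        else:
            missed += 1
    spurious = 0
    for s, e in _events(pred):
        if truth[s:e].sum() < overlap * (e - s):
            spurious += 1
    return {"matched": matched, "missed": missed, "spurious": spurious}


def align_clusters_to_states(pred_labels, truth_labels) -> dict[int, int]:
    """Map each predicted cluster to the truth state it overlaps most.

    Ties break toward the lower truth state id. The mapping generalizes the
    manual grouping of several clusters onto one behavioral state.
    """
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise ValueError("label sequences must align")
    if pred.size == 0:
        raise ValueError("empty labels")
    mapping: dict[int, int] = {}
    states = np.unique(truth)
    for cluster in np.unique(pred):
        mask = pred == cluster
        counts = np.array([np.sum(truth[mask] == s) for s in states])
        mapping[int(cluster)] = int(states[int(np.argmax(counts))])
    return mapping


def grouped_matching(
    pred_labels, truth_labels, positive_state, mapping: dict[int, int] | None = None
) -> MatchingMatrix:
    """Matching matrix after grouping predicted clusters onto truth states."""
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if mapping is None:
        mapping = align_clusters_to_states(pred, truth)
    grouped = np.array([mapping[int(c)] for c in pred])
    return matching_matrix(grouped == positive_state, truth == positive_state)
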