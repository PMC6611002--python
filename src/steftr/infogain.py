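"""Single-threshold information-gain feature extraction.

Every numeric feature column is evaluated as a decision stump: candidate
thresholds are the midpoints between consecutive distinct sorted values, and
the reported gain is the reduction in class entropy

    H = - sum_n p_n log2 p_n

achieved by the best threshold (ties go to the smaller threshold). Whether a
feature counts as *extracted* is decided by the Fayyad-Irani minimum
description length (MDL) acceptance rule for the best split: with continuous
noise features the raw best-split gain is almost surely positive, so a
penalized acceptance criterion is what makes "positive information gain"
selective. Rows with a missing value are excluded from that feature's
evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def entropy(class_counts) -> float:
    """Shannon entropy in bits of a count vector; 0*log(0) == 0."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class SplitEvaluation:
    """Best single-threshold split of one feature against the condition labels."""

    feature: str
    threshold: float
    gain: float
    parent_entropy: float
    n_per_class: tuple[int, ...]
    n_used: int
    mdl_accepted: bool


def _binary_entropies(left_counts: np.ndarray, right_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    def h(counts: np.ndarray) -> np.ndarray:
        total = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
            terms = np.where(p > 0, -p * np.log2(p), 0.0)
        return terms.sum(axis=1)

    return h(left_counts), h(right_counts)


def information_gain(values, condition_labels, feature: str = "") -> SplitEvaluation:
    """Exhaustive best-threshold information gain of one feature.

    ``condition_labels`` may be any hashable labels (two or more classes; the
    two-condition comparison is the common case). A constant feature yields
    zero gain with the constant reported as the threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(condition_labels)
    if len(values) != len(labels):
        raise ValueError("values and condition labels must align")
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    if len(values) < 2:
        raise ValueError("need at least 2 usable rows")
    classes, y = np.unique(labels, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise ValueError("both conditions must be present")
    n = len(values)
    class_counts = np.bincount(y, minlength=k)
    parent = entropy(class_counts)

    order = np.argsort(values, kind="mergesort")
    sv, sy = values[order], y[order]
    onehot = np.zeros((n, k))
    onehot[np.arange(n), sy] = 1.0
    cum = np.cumsum(onehot, axis=0)

    distinct = np.flatnonzero(np.diff(sv) > 0)
    if len(distinct) == 0:
        return SplitEvaluation(feature, float(sv[0]), 0.0, parent, tuple(class_counts), n, False)
    left = cum[distinct]
    right = class_counts - left
    h_left, h_right = _binary_entropies(left, right)
    n_left = left.sum(axis=1)
    gains = parent - (n_left * h_left + (n - n_left) * h_right) / n

    best = int(np.argmax(gains))  # argmax returns the first (= smallest threshold) tie
    threshold = float((sv[distinct[best]] + sv[distinct[best] + 1]) / 2.0)
    gain = float(max(gains[best], 0.0))

    accepted = _mdl_accept(
        gain, parent, h_left[best], h_right[best], left[best], right[best], n, k
    )
    return SplitEvaluation(feature, threshold, gain, parent, tuple(class_counts), n, accepted)


def _mdl_accept(
    gain: float,
    parent: float,
    h_left: float,
    h_right: float,
    left: np.ndarray,
    right: np.ndarray,
    n: int,
    k: int,
) -> bool:
    """Fayyad-Irani MDL stopping criterion for accepting the best binary split."""
    if gain <= 0:
        return False
    k1 = int(np.count_nonzero(left))
    k2 = int(np.count_nonzero(right))
    delta = np.log2(3.0**k - 2.0) - (k * parent - k1 * h_left - k2 * h_right)
    threshold = (np.log2(n - 1) + delta) / n
    return gain > threshold


@dataclass
class InfoGainReport:
    """Per-feature split evaluations for a two-condition comparison."""

    evaluations: list[SplitEvaluation]
    conditions: tuple = ()
    n_per_condition: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.evaluations = sorted(self.evaluations, key=lambda e: (-e.gain, e.feature))

    @property
    def extracted(self) -> list[str]:
        """Features whose best split passes the MDL acceptance rule."""
        return [e.feature for e in self.evaluations if e.mdl_accepted]

    def feature_names(self) -> set[str]:
        return {e.feature for e in self.evaluations}

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature in the gain-sorted report."""
        for i, e in enumerate(self.evaluations, start=1):
            if e.feature == feature:
                return i
        raise KeyError(feature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [e.feature for e in self.evaluations],
                "threshold": [e.threshold for e in self.evaluations],
                "gain": [e.gain for e in self.evaluations],
                "extracted": [e.mdl_accepted for e in self.evaluations],
                "n_used": [e.n_used for e in self.evaluations],
            }
        )


def extract_condition_features(
    table: pd.DataFrame, condition_col: str = "condition"
) -> InfoGainReport:
    """Evaluate every numeric feature column of a segment-feature table.

    ``table`` has one row per analysis unit (segment/round/flight) and a
    binary condition column; all other numeric columns are scored.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    if condition_col not in table.columns:
        raise ValueError(f"missing condition column {condition_col!r}")
    cond = table[condition_col].to_numpy()
    classes, counts = np.unique(cond, return_counts=True)
    evaluations = []
    for col in table.columns:
        if col == condition_col or not pd.api.types.is_numeric_dtype(table[col]):
            continue
        vals = table[col].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        if keep.sum() < 2 or len(np.unique(cond[keep])) < 2:
            evaluations.append(
                SplitEvaluation(col, np.nan, 0.0, 0.0, tuple(counts), int(keep.sum()), False)
            )
            continue
        evaluations.append(information_gain(vals, cond, feature=col))
    return InfoGainReport(evaluations, conditions=tuple(classes), n_per_condition=tuple(counts))


def common_learning_features(report_a: InfoGainReport, report_b: InfoGainReport) -> list[str]:
    """Extracted features shared by two comparisons (e.g. naive-vs-exposed and
    mock-vs-exposed): the features modulated consistently across both."""
    if report_a.feature_names() != report_b.feature_names():
        raise ValueError("reports cover different feature sets")
    return sorted(set(report_a.extracted) & set(report_b.extracted))


def permutation_null_max_gain(
    table: pd.DataFrame,
    condition_col: str = "condition",
    n_permutations: int = 200,
    seed: int = 1,
) -> np.ndarray:
    """Null distribution of the per-permutation maximum gain across features.

    Shuffles the condition labels ``n_permutations`` times; useful to
    calibrate how large a gain random labels can produce.
    """
    rng = np.random.default_rng(seed)
    cond = table[condition_col].to_numpy()
    numeric = [
        c
        for c in table.columns
        if c != condition_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    out = np.empty(n_permutations)
    for p in range(n_permutations):
        shuffled = rng.permutation(cond)
        best = 0.0
        for col in numeric:
            vals = table[col].to_numpy(dtype=float)
            keep = np.isfinite(vals)
            if keep.sum() < 2 or len(np.unique(shuffled[keep])) < 2:
                continue
            best = max(best, information_gain(vals, shuffled, feature=col).gain)
        out[p] = best
    return out
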