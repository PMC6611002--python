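import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import steftr
from steftr.infogain import entropy, information_gain


def brute_force_gain(values, labels):
    """Exhaustive stump search: every midpoint threshold, recomputed naively."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    parent = entropy([np.sum(labels == c) for c in classes])
    sv = np.unique(values)
    best = 0.0
    for a, b in zip(sv[:-1], sv[1:]):
        thr = (a + b) / 2
        left, right = labels[values <= thr], labels[values > thr]
        h = 0.0
        for part in (left, right):
            h += len(part) / len(values) * entropy([np.sum(part == c) for c in classes])
        best = max(best, parent - h)
    return best


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5], 1.0), ([10, 0], 0.0), ([1, 1, 1, 1], 2.0), ([3, 1], 0.8112781244591328)],
    )
    def test_known_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            entropy([0, 0])


class TestInformationGain:
    def test_perfect_split(self):
        ev = information_gain([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert ev.gain == pytest.approx(1.0)
        assert ev.threshold == pytest.approx(2.5)
        assert ev.gain == pytest.approx(ev.parent_entropy)

    def test_constant_feature_has_zero_gain(self):
        ev = information_gain([7, 7, 7, 7], ["A", "B", "A", "B"])
        assert ev.gain == 0.0
        assert ev.threshold == 7.0

    def test_alternating_case_matches_brute_force(self):
        values, labels = [1, 2, 3, 4, 5, 6], ["A", "B", "A", "B", "A", "B"]
        assert information_gain(values, labels).gain == pytest.approx(
            brute_force_gain(values, labels)
        )

    def test_random_small_tables_match_brute_force_exactly(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            values = np.round(rng.normal(0, 1, n), 2)
            labels = rng.choice(["A", "B"], n)
            if len(np.unique(labels)) < 2:
                continue
            ev = information_gain(values, labels)
            assert ev.gain == pytest.approx(brute_force_gain(values, labels), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_leaves_gain_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, 20)
        labels = rng.choice(["A", "B"], 20)
        if len(np.unique(labels)) < 2:
            return
        g0 = information_gain(values, labels).gain
        g1 = information_gain(np.exp(values), labels).gain
        assert g0 == pytest.approx(g1, abs=1e-12)

    def test_gain_nonnegative_and_bounded_by_parent(self, rng):
        for _ in range(50):
            values = rng.normal(0, 1, 30)
            labels = rng.choice(["A", "B"], 30)
            if len(np.unique(labels)) < 2:
                continue
            ev = information_gain(values, labels)
            assert 0.0 <= ev.gain <= ev.parent_entropy + 1e-12

    def test_missing_values_excluded(self):
        ev = information_gain([1, 2, np.nan, 4], ["A", "A", "B", "B"])
        assert ev.n_used == 3


class TestExtractConditionFeatures:
    def test_single_perfect_feature(self):
        df = pd.DataFrame({"f": [1, 2, 3, 4], "condition": ["A", "A", "B", "B"]})
        rep = steftr.extract_condition_features(df)
        assert len(rep.evaluations) == 1
        assert rep.evaluations[0].gain == pytest.approx(rep.evaluations[0].parent_entropy)
        assert rep.extracted == ["f"]

    def test_planted_shift_ranks_first_among_noise(self, rng):
        n = 200
        df = pd.DataFrame({f"noise{i}": rng.normal(0, 1, n) for i in range(20)})
        cond = np.repeat(["A", "B"], n // 2)
        df["shifted"] = rng.normal(0, 1, n) + np.where(cond == "B", 1.5, 0.0)
        df["condition"] = cond
        rep = steftr.extract_condition_features(df)
        assert rep.evaluations[0].feature == "shifted"
        assert rep.rank_of("shifted") == 1

    def test_random_labels_extract_almost_nothing(self, rng):
        n = 200
        df = pd.DataFrame({f"noise{i}": rng.normal(0, 1, n) for i in range(40)})
        df["condition"] = rng.choice(["A", "B"], n)
        rep = steftr.extract_condition_features(df)
        assert len(rep.extracted) <= 2  # <= 5% of 40 columns

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            steftr.extract_condition_features(pd.DataFrame({"condition": []}))


class TestCommonLearningFeatures:
    @staticmethod
    def _report(extracted, universe):
        from steftr.infogain import InfoGainReport, SplitEvaluation

        return InfoGainReport(
            [
                SplitEvaluation(f, 0.0, 0.5 if f in extracted else 0.0, 1.0, (5, 5), 10, f in extracted)
                for f in universe
            ]
        )

    def test_intersection(self):
        u = ["a", "b", "c", "d"]
        got = steftr.common_learning_features(self._report({"a", "b", "c"}, u), self._report({"b", "c", "d"}, u))
        assert got == ["b", "c"]

    def test_disjoint_sets_yield_empty(self):
        u = ["a", "b"]
        assert steftr.common_learning_features(self._report({"a"}, u), self._report({"b"}, u)) == []

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            steftr.common_learning_features(self._report(set(), ["a"]), self._report(set(), ["b"]))


class TestPermutationNull:
    def test_planted_gain_exceeds_permutation_null(self, rng):
        n = 120
        df = pd.DataFrame({"f": rng.normal(0, 1, n), "g": rng.normal(0, 1, n)})
        cond = np.repeat(["A", "B"], n // 2)
        df["f"] += np.where(cond == "B", 2.0, 0.0)
        df["condition"] = cond
        observed = steftr.extract_condition_features(df).evaluations[0].gain
        null = steftr.permutation_null_max_gain(df, n_permutations=100, seed=1)
        assert np.median(null) < observed
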