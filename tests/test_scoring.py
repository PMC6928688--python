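"""NDCG rank-consistency metric, score-function selection, threshold stage."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vscascade.fixtures import gen_score_table
from vscascade.scoring import (
    DegenerateRelevanceError,
    SchemaError,
    ScoreTable,
    calibrate_cutoff,
    dcg,
    ndcg,
    pic50,
    select_scoring_function,
    threshold_stage,
)


def brute_dcg(rels):
    """Independent evaluation: rel_1 + sum_{i>=2} rel_i / log2(i)."""
    total = rels[0]
    for i in range(2, len(rels) + 1):
        total += rels[i - 1] / math.log2(i)
    return total


class TestDcg:
    def test_hand_computed(self):
        assert dcg([3, 2, 1]) == pytest.approx(3 + 2 / 1 + 1 / math.log2(3), abs=1e-12)
        assert dcg([3, 2, 1]) == pytest.approx(5.6309, abs=5e-4)

    def test_singleton_and_zeros(self):
        assert dcg([7.5]) == 7.5
        assert dcg([0, 0, 0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dcg([])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=8))
    def test_matches_independent_oracle(self, rels):
        assert dcg(rels) == pytest.approx(brute_dcg(rels), abs=1e-9)


class TestNdcg:
    def test_hand_computed_reversed_order(self):
        rels = {"a": 3.0, "b": 2.0, "c": 1.0}
        val = ndcg(["c", "b", "a"], rels)
        expected = (1 + 2 + 3 / math.log2(3)) / (3 + 2 + 1 / math.log2(3))
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.869, abs=5e-4)

    def test_sorted_order_is_exactly_one(self):
        rels = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert ndcg(["a", "b", "c"], rels) == 1.0

    def test_single_molecule(self):
        assert ndcg(["x"], {"x": 4.2}) == 1.0

    def test_all_zero_relevance_rejected(self):
        with pytest.raises(DegenerateRelevanceError):
            ndcg(["a", "b"], {"a": 0.0, "b": 0.0})

    def test_all_orderings_match_brute_force(self):
        """Every permutation of a 5-item relevance vector agrees with the
        independent oracle to 1e-12.  NDCG reaches exactly 1 for the sorted
        order and for the top-2 swap only, since ranks 1 and 2 share the
        same discount weight."""
        rels = {c: r for c, r in zip("abcde", [5.0, 4.0, 3.0, 2.0, 1.0])}
        ideal = brute_dcg(sorted(rels.values(), reverse=True))
        perfect = {tuple("abcde"), tuple("bacde")}
        for perm in itertools.permutations(rels):
            expected = brute_dcg([rels[i] for i in perm]) / ideal
            assert ndcg(list(perm), rels) == pytest.approx(expected, abs=1e-12)
            assert (ndcg(list(perm), rels) == 1.0) == (perm in perfect)

    def test_scale_invariance_under_monotone_score_transform(self):
        """NDCG depends on scores only through the ranking they induce."""
        ic50s = {f"m{i}": 10 ** (-i / 4) for i in range(12)}
        table = gen_score_table(ic50s, n_columns=2, rank_noise=(1.0, 2.0), seed=5)
        rels = {i: pic50(v) for i, v in ic50s.items()}
        before = ndcg(table.ranking("fn1"), rels)
        warped = ScoreTable(
            data=pd.DataFrame({"fn1": np.exp(table.data["fn1"] / 3.0)}, index=table.data.index),
            direction={"fn1": "higher_is_better"},
        )
        assert ndcg(warped.ranking("fn1"), rels) == pytest.approx(before, abs=1e-12)


class TestSelectScoringFunction:
    def test_noise_free_column_selected(self):
        ic50s = {f"m{i}": 10 ** (-i / 5) for i in range(20)}
        table = gen_score_table(ic50s, n_columns=4, rank_noise=(0.0, 1.0, 2.0, 4.0), seed=1)
        best, per = select_scoring_function(table, ic50s)
        assert best == "fn1" and per["fn1"] == pytest.approx(1.0)

    def test_direction_symmetry(self):
        ic50s = {f"m{i}": 10 ** (-i / 5) for i in range(10)}
        table = gen_score_table(ic50s, n_columns=1, rank_noise=(1.0,), seed=2)
        flipped = ScoreTable(
            data=pd.DataFrame({"neg": -table.data["fn1"]}, index=table.data.index),
            direction={"neg": "lower_is_better"},
        )
        _, a = select_scoring_function(table, ic50s)
        _, b = select_scoring_function(flipped, ic50s)
        assert a["fn1"] == pytest.approx(b["neg"], abs=1e-12)

    def test_selection_matches_brute_force_oracle(self):
        """20-molecule fixture with 4 noisy columns: argmax of
        independently computed NDCGs equals the selection."""
        ic50s = {f"m{i}": 10 ** ((i % 7) / 3 - 2) for i in range(20)}
        table = gen_score_table(ic50s, n_columns=4, rank_noise=(0.5, 1.5, 3.0, 6.0), seed=3)
        rels = {i: pic50(v) for i, v in ic50s.items()}
        ideal = brute_dcg(sorted(rels.values(), reverse=True))
        oracle = {}
        for col in table.data.columns:
            order = list(table.data[col].sort_values(ascending=False, kind="stable").index)
            oracle[col] = brute_dcg([rels[i] for i in order]) / ideal
        best, per = select_scoring_function(table, ic50s)
        for col in oracle:
            assert per[col] == pytest.approx(oracle[col], abs=1e-12)
        assert best == max(oracle, key=oracle.get)

    def test_molecule_with_missing_score_excluded(self):
        ic50s = {"a": 1.0, "b": 0.1, "c": 0.01}
        df = pd.DataFrame({"s": [1.0, np.nan, 3.0]}, index=["a", "b", "c"])
        table = ScoreTable(df, {"s": "higher_is_better"})
        best, per = select_scoring_function(table, ic50s)
        assert best == "s" and per["s"] == 1.0  # a < c in potency, scores agree


class TestThresholdStage:
    def test_boundary_inclusive_and_monotone(self):
        df = pd.DataFrame({"s": np.arange(10.0)}, index=[f"m{i}" for i in range(10)])
        table = ScoreTable(df, {"s": "higher_is_better"})
        assert set(threshold_stage(table, "s", -1.0)) == set(df.index)
        assert threshold_stage(table, "s", 100.0) == []
        surv5 = set(threshold_stage(table, "s", 5.0))
        assert "m5" in surv5  # boundary survives
        # monotone: a more permissive cutoff gives a superset
        assert surv5 <= set(threshold_stage(table, "s", 4.0))

    def test_lower_is_better_direction(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("abc"))
        table = ScoreTable(df, {"s": "lower_is_better"})
        assert threshold_stage(table, "s", 2.0) == ["a", "b"]

    def test_unknown_column(self):
        df = pd.DataFrame({"s": [1.0]}, index=["a"])
        with pytest.raises(SchemaError):
            threshold_stage(ScoreTable(df, {"s": "higher_is_better"}), "nope", 0.0)


class TestCalibrateCutoff:
    def test_perfect_separation(self):
        df = pd.DataFrame({"s": [1.0, 2, 3, 10, 11, 12]}, index=list("abcdef"))
        table = ScoreTable(df, {"s": "higher_is_better"})
        labels = {"a": False, "b": False, "c": False, "d": True, "e": True, "f": True}
        cutoff = calibrate_cutoff(table, "s", labels, objective="max_EF")
        surv = set(threshold_stage(table, "s", cutoff))
        assert surv == {"d", "e", "f"}

    def test_random_labels_give_ef_near_one(self):
        rng = np.random.default_rng(9)
        n = 400
        df = pd.DataFrame({"s": rng.normal(size=n)}, index=[f"m{i}" for i in range(n)])
        table = ScoreTable(df, {"s": "higher_is_better"})
        labels = {f"m{i}": bool(rng.random() < 0.5) for i in range(n)}
        cutoff = calibrate_cutoff(table, "s", labels, objective="max_youden")
        surv = set(threshold_stage(table, "s", cutoff))
        tp = sum(labels[i] for i in surv)
        ef = (tp / len(surv)) / (sum(labels.values()) / n)
        assert 0.7 < ef < 1.45  # no real signal -> EF hovers near 1

    def test_target_yield_smallest_survivor_set(self):
        df = pd.DataFrame({"s": np.arange(10.0)}, index=[f"m{i}" for i in range(10)])
        table = ScoreTable(df, {"s": "higher_is_better"})
        labels = {f"m{i}": i >= 4 for i in range(10)}  # 6 actives at the top
        cutoff = calibrate_cutoff(table, "s", labels, objective="target_yield",
                                  target_yield=0.82)
        surv = threshold_stage(table, "s", cutoff)
        tp = sum(labels[i] for i in surv)
        assert tp / 6 >= 0.82
        # strictest such cutoff: dropping one more molecule would break the target
        stricter = [c for c in sorted(set(df["s"])) if c > cutoff]
        if stricter:
            tp2 = sum(labels[i] for i in threshold_stage(table, "s", stricter[0]))
            assert tp2 / 6 < 0.82

    def test_single_class_rejected(self):
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        table = ScoreTable(df, {"s": "higher_is_better"})
        with pytest.raises(ValueError):
            calibrate_cutoff(table, "s", {"a": True, "b": True})


def test_pic50_conversion():
    assert pic50(1.0) == pytest.approx(6.0)    # 1 uM -> 1e-6 M
    assert pic50(0.001) == pytest.approx(9.0)  # 1 nM
    with pytest.raises(ValueError):
        pic50(0.0)
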