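"""Cascade composition, confusion accounting and screening metrics."""

import itertools
import random

import pytest
from rdkit import Chem

from vscascade.cascade import (
    AccountingError,
    CascadeReport,
    ConfusionCounts,
    Stage,
    confusion,
    lipinski_filter,
    metrics,
    order_stages,
    run_cascade,
)
from vscascade.dataset import MoleculeRecord
from vscascade.fixtures import gen_chem_library


def toy_library(n=100, seed=0):
    rng = random.Random(seed)
    lib = [MoleculeRecord(id=f"m{i:03d}") for i in range(n)]
    truth = {m.id: rng.random() < 0.3 for m in lib}
    return lib, truth


def seeded_stage(name, pass_rate, seed):
    rng = random.Random(seed)
    decisions = {}

    def predicate(mol):
        if mol.id not in decisions:
            decisions[mol.id] = rng.random() < pass_rate
        return decisions[mol.id]

    return Stage(name=name, predicate=predicate)


class TestConfusion:
    def test_all_correct(self):
        pred = {"a": True, "b": True, "c": False}
        truth = {"a": True, "b": True, "c": False}
        assert confusion(pred, truth) == ConfusionCounts(2, 0, 1, 0)

    def test_random_predictions_match_direct_tally(self):
        rng = random.Random(5)
        truth = {f"m{i}": i < 25 for i in range(50)}
        pred = {k: rng.random() < 0.5 for k in truth}
        c = confusion(pred, truth)
        tp = sum(pred[k] and truth[k] for k in truth)
        fp = sum(pred[k] and not truth[k] for k in truth)
        fn = sum(not pred[k] and truth[k] for k in truth)
        tn = sum(not pred[k] and not truth[k] for k in truth)
        assert (c.TP, c.FP, c.FN, c.TN) == (tp, fp, fn, tn)

    def test_missing_truth_flag_raises(self):
        with pytest.raises(AccountingError, match="x"):
            confusion({"x": True}, {})


class TestMetrics:
    def test_definitional_identities(self):
        c = ConfusionCounts(30, 10, 50, 10)
        m = metrics(c, base_fraction=0.4)
        assert m.SE == pytest.approx(75.0)
        assert m.SP == pytest.approx(100 * 50 / 60)
        assert m.Q == pytest.approx(80.0)
        assert m.yield_pct == m.SE
        assert m.hit_rate == pytest.approx(75.0)
        assert m.EF == pytest.approx(0.75 / 0.4)

    def test_ef_is_one_at_base_rate(self):
        # hit rate equal to the base fraction -> EF exactly 1
        m = metrics(ConfusionCounts(30, 70, 70, 30), base_fraction=0.5)
        assert m.EF == pytest.approx(1.0)

    def test_empty_survivor_set_warns(self):
        with pytest.warns(UserWarning, match="hit rate"):
            m = metrics(ConfusionCounts(0, 10, 90, 0), base_fraction=0.1)
        assert m.hit_rate != m.hit_rate  # NaN

    def test_bad_base_fraction(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(1, 1, 1, 1), base_fraction=1.0)


class TestRunCascade:
    def test_all_pass_stages_keep_library(self):
        lib, truth = toy_library(30)
        st = Stage("open", lambda m: True)
        rep = run_cascade([st, st], lib, truth=truth)
        assert rep.survivors() == [m.id for m in lib]

    def test_oracle_stage_zeroes_fp(self):
        lib, truth = toy_library(50)
        oracle = Stage("oracle", lambda m: truth[m.id])
        noisy = seeded_stage("noisy", 0.9, 1)
        rep = run_cascade([oracle, noisy], lib, truth=truth)
        assert all(sr.counts.FP == 0 for sr in rep.stages)

    def test_survivor_monotonicity_on_seeded_random_cascades(self):
        for seed in range(5):
            lib, truth = toy_library(100, seed)
            stages = [seeded_stage(f"s{k}", 0.6, seed * 10 + k) for k in range(3)]
            rep = run_cascade(stages, lib, truth=truth)
            prev = {m.id for m in lib}
            for sr in rep.stages:
                assert set(sr.surviving_ids) <= prev
                prev = set(sr.surviving_ids)

    def test_matches_independent_sequential_filtering(self):
        """Oracle: applying the three predicates one molecule at a time in
        sequence gives the same survivor set as the cascade run."""
        lib, truth = toy_library(100, 7)
        stages = [seeded_stage(f"s{k}", 0.5, 70 + k) for k in range(3)]
        rep = run_cascade(stages, lib, truth=truth)
        expected = [m.id for m in lib]
        for st in stages:
            expected = [i for i in expected if st.predicate(MoleculeRecord(id=i))]
        assert rep.survivors() == expected

    def test_stage1_actives_accounting(self):
        lib, truth = toy_library(80, 2)
        st = seeded_stage("s", 0.5, 3)
        rep = run_cascade([st], lib, truth=truth)
        c = rep.stages[0].counts
        assert c.TP + c.FN == sum(truth.values())

    def test_failing_predicate_counts_as_negative(self):
        lib, truth = toy_library(10, 1)

        def boom(mol):
            raise RuntimeError("bad molecule")

        rep = run_cascade([Stage("boom", boom)], lib, truth=truth)
        assert rep.survivors() == []

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError):
            run_cascade([], [], truth=None)


class TestOrderStages:
    def test_matches_exhaustive_enumeration(self):
        """3-stage toy with planted pass behavior: the returned ordering
        equals the EF-argmax over all 6 permutations computed directly."""
        lib, truth = toy_library(120, 3)
        stages = [
            Stage("perfect", lambda m: truth[m.id]),
            seeded_stage("loose", 0.8, 31),
            seeded_stage("tight", 0.3, 32),
        ]
        best, rows = order_stages(stages, lib, truth, criterion="max_EF")
        assert len(rows) == 6
        efs = {tuple(r["ordering"]): r["EF"] for r in rows}
        assert efs[tuple(s.name for s in best)] == max(efs.values())

    def test_cheap_stage_first_under_cost_criterion(self):
        lib, truth = toy_library(100, 4)
        cheap = Stage("cheap", lambda m: truth[m.id], cost_hint=1.0)
        costly = Stage("costly", lambda m: truth[m.id], cost_hint=100.0)
        best, _ = order_stages([costly, cheap], lib, truth, criterion="min_time_then_EF")
        assert [s.name for s in best] == ["cheap", "costly"]

    def test_identical_stages_tie_break_by_name(self):
        lib, truth = toy_library(40, 5)
        a = Stage("a", lambda m: True)
        b = Stage("b", lambda m: True)
        best, _ = order_stages([b, a], lib, truth, criterion="max_EF")
        assert [s.name for s in best] == ["a", "b"]


class TestLipinskiFilter:
    def mk(self, i, smi):
        return MoleculeRecord(id=str(i), structure=Chem.MolFromSmiles(smi))

    def test_small_polar_molecule_passes(self):
        assert len(lipinski_filter([self.mk(0, "CCO")])) == 1

    def test_gross_violator_fails(self):
        # long lipophilic chain: MW > 500 and logP > 5 -> two violations
        big = self.mk(0, "C" * 40)
        assert lipinski_filter([big]) == []

    def test_single_violation_tolerated_by_default_not_strict(self):
        # slightly heavy but otherwise compliant molecule
        one_violation = self.mk(0, "C" * 26)  # MW ~ 367, logP > 5: one violation
        from rdkit.Chem import Crippen, Descriptors
        assert Crippen.MolLogP(one_violation.structure) > 5
        assert Descriptors.MolWt(one_violation.structure) <= 500
        assert len(lipinski_filter([one_violation], max_violations=1)) == 1
        assert lipinski_filter([one_violation], max_violations=0) == []

    def test_hand_tabulated_fixture(self):
        """Survivors equal a hand evaluation of the four rules over a small
        library with known properties."""
        from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
        lib = gen_chem_library(5, 5, seed=13)
        survivors = {m.id for m in lipinski_filter(lib, max_violations=1)}
        expected = set()
        for m in lib:
            v = sum([
                Descriptors.MolWt(m.structure) > 500,
                Crippen.MolLogP(m.structure) > 5,
                rdMolDescriptors.CalcNumHBD(m.structure) > 5,
                rdMolDescriptors.CalcNumHBA(m.structure) > 10,
            ])
            if v <= 1:
                expected.add(m.id)
        assert survivors == expected

    def test_unparsable_skipped(self):
        assert lipinski_filter([MoleculeRecord(id="x", structure=None)]) == []
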