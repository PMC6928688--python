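"""Cascade composition and screening metrics.

A virtual-screening cascade is an ordered list of stages, each a pass/fail
predicate over molecules (an SVM model, a pharmacophore query set, a
docking-score threshold ...).  Each stage sees only the survivors of the
previous one, so an early cheap high-specificity stage shrinks the work for
the expensive later stages.  With ground truth supplied, per-stage
confusion counts yield the standard retrieval metrics:

    SE  = 100 * TP/(TP+FN)        sensitivity (== yield)
    SP  = 100 * TN/(TN+FP)        specificity
    Q   = 100 * (TP+TN)/total     overall accuracy
    hit rate = 100 * TP/(TP+FP)   purity of the survivor set
    EF  = (hit rate/100) / base_fraction

where base_fraction is the fraction of known actives in the screened set,
always passed explicitly.
"""

from __future__ import annotations

import itertools
import logging
import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .dataset import MoleculeRecord

logger = logging.getLogger(__name__)


class AccountingError(ValueError):
    """Prediction and truth id sets disagree."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class ScreeningMetrics:
    """Percentages are unrounded; use :meth:`rounded` for display."""

    SE: float
    SP: float
    Q: float
    yield_pct: float
    hit_rate: float  # NaN when the survivor set is empty
    EF: float
    base_fraction: float

    def rounded(self) -> dict[str, float]:
        out = {k: round(getattr(self, k), 1) for k in ("SE", "SP", "Q", "yield_pct", "hit_rate")}
        out["EF"] = round(self.EF, 2)
        return out


def confusion(pred: Mapping[str, bool], truth: Mapping[str, bool]) -> ConfusionCounts:
    """Exact confusion counts from per-id predictions and truth flags."""
    missing = [i for i in pred if i not in truth]
    if missing:
        raise AccountingError(f"ids without truth flags: {sorted(missing)[:10]}")
    tp = fn = tn = fp = 0
    for mol_id, p in pred.items():
        if truth[mol_id]:
            tp, fn = (tp + 1, fn) if p else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if p else (fp, tn + 1)
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


def metrics(counts: ConfusionCounts, base_fraction: float) -> ScreeningMetrics:
    """Screening metrics from confusion counts and the active base rate."""
    if not (0 < base_fraction < 1):
        raise ValueError("base_fraction must lie in (0, 1)")
    P, N = counts.positives, counts.negatives
    se = 100.0 * counts.TP / P if P else math.nan
    sp = 100.0 * counts.TN / N if N else math.nan
    q = 100.0 * (counts.TP + counts.TN) / (P + N) if P + N else math.nan
    predicted_pos = counts.TP + counts.FP
    if predicted_pos == 0:
        warnings.warn("no predicted positives: hit rate undefined", stacklevel=2)
        hit = math.nan
        ef = math.nan
    else:
        hit = 100.0 * counts.TP / predicted_pos
        ef = (hit / 100.0) / base_fraction
    return ScreeningMetrics(SE=se, SP=sp, Q=q, yield_pct=se, hit_rate=hit, EF=ef, base_fraction=base_fraction)


@dataclass
class Stage:
    """One cascade filter.

    ``predicate`` maps a molecule to pass/fail; an exception inside it
    counts the molecule as screen-negative so a malformed input degrades
    a cascade instead of crashing it.  ``cost_hint`` is a relative runtime
    weight used by cost-aware stage ordering.
    """

    name: str
    predicate: Callable[[MoleculeRecord], bool]
    cost_hint: float = 1.0

    def apply(self, molecules: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
        survivors = []
        for mol in molecules:
            try:
                ok = bool(self.predicate(mol))
            except Exception:
                logger.warning("stage %s failed on %s; counted as fail", self.name, mol.id, exc_info=True)
                ok = False
            if ok:
                survivors.append(mol)
        return survivors


@dataclass
class StageReport:
    name: str
    input_ids: list[str]
    surviving_ids: list[str]
    counts: ConfusionCounts | None = None
    stage_metrics: ScreeningMetrics | None = None
    seconds: float = 0.0


@dataclass
class CascadeReport:
    stages: list[StageReport] = field(default_factory=list)
    ordering: list[str] = field(default_factory=list)
    overall_counts: ConfusionCounts | None = None
    overall_metrics: ScreeningMetrics | None = None

    def survivors(self) -> list[str]:
        return self.stages[-1].surviving_ids if self.stages else []


def run_cascade(
    stages: Sequence[Stage],
    library: Sequence[MoleculeRecord],
    truth: Mapping[str, bool] | None = None,
    base_fraction: float | None = None,
) -> CascadeReport:
    """Apply stages sequentially, with per-stage survivor accounting.

    When ``truth`` is given, each stage's confusion is computed over the
    *original* library (molecules eliminated before a stage count as that
    stage's negatives), so overall counts equal the last stage's counts.
    ``base_fraction`` defaults to the truth's active fraction.
    """
    if not stages:
        raise ValueError("stages must be nonempty")
    if truth is not None:
        missing = [m.id for m in library if m.id not in truth]
        if missing:
            raise AccountingError(f"library ids without truth flags: {missing[:10]}")
        if base_fraction is None:
            base_fraction = sum(truth[m.id] for m in library) / len(library)

    report = CascadeReport(ordering=[s.name for s in stages])
    current = list(library)
    for stage in stages:
        t0 = time.perf_counter()
        survivors = stage.apply(current)
        dt = time.perf_counter() - t0
        sr = StageReport(
            name=stage.name,
            input_ids=[m.id for m in current],
            surviving_ids=[m.id for m in survivors],
            seconds=dt,
        )
        if truth is not None:
            surviving = {m.id for m in survivors}
            pred = {m.id: (m.id in surviving) for m in library}
            sr.counts = confusion(pred, truth)
            sr.stage_metrics = metrics(sr.counts, base_fraction)
        logger.info("stage %s: %d -> %d molecules (%.3fs)", stage.name, len(current), len(survivors), dt)
        report.stages.append(sr)
        current = survivors
    if truth is not None:
        report.overall_counts = report.stages[-1].counts
        report.overall_metrics = report.stages[-1].stage_metrics
    return report


def order_stages(
    stages: Sequence[Stage],
    validation: Sequence[MoleculeRecord],
    truth: Mapping[str, bool],
    criterion: str = "max_EF",
    base_fraction: float | None = None,
) -> tuple[list[Stage], list[dict]]:
    """Evaluate every stage permutation on a labelled validation library.

    ``max_EF`` picks the ordering with the best final enrichment factor;
    ``min_time_then_EF`` first minimizes total cost (sum over stages of
    cost_hint x stage input size), breaking ties by EF.  All ties fall back
    to the lexicographically smallest name sequence, so the result is
    deterministic.  Returns the winning ordering and the full comparison
    table (one dict per permutation).
    """
    if len(stages) < 2:
        raise ValueError("need at least two stages to order")
    if criterion not in ("max_EF", "min_time_then_EF"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows = []
    for perm in itertools.permutations(stages):
        rep = run_cascade(perm, validation, truth=truth, base_fraction=base_fraction)
        cost = sum(s.cost_hint * len(sr.input_ids) for s, sr in zip(perm, rep.stages))
        ef = rep.overall_metrics.EF
        rows.append({
            "ordering": [s.name for s in perm],
            "EF": ef,
            "cost": cost,
            "survivors": len(rep.survivors()),
            "report": rep,
        })

    def key(row: dict):
        ef = row["EF"] if not math.isnan(row["EF"]) else -math.inf
        if criterion == "max_EF":
            return (-ef, row["ordering"])
        return (row["cost"], -ef, row["ordering"])

    rows.sort(key=key)
    best_names = rows[0]["ordering"]
    by_name = {s.name: s for s in stages}
    return [by_name[n] for n in best_names], rows


def lipinski_filter(molecules: Iterable[MoleculeRecord], max_violations: int = 1) -> list[MoleculeRecord]:
    """Drug-likeness filter: MW <= 500 Da, logP <= 5, H-bond donors <= 5,
    acceptors <= 10, with up to ``max_violations`` rule breaks tolerated
    (``max_violations=0`` is the strict variant)."""
    survivors = []
    for rec in molecules:
        if rec.structure is None:
            logger.warning("lipinski_filter: skipping unparsable molecule %s", rec.id)
            continue
        m = rec.structure
        violations = sum([
            Descriptors.MolWt(m) > 500.0,
            Crippen.MolLogP(m) > 5.0,
            rdMolDescriptors.CalcNumHBD(m) > 5,
            rdMolDescriptors.CalcNumHBA(m) > 10,
        ])
        if violations <= max_violations:
            survivors.append(rec)
    return survivors
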