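"""External score-table ingestion and NDCG-based score-function selection.

Docking (or any other) scores arrive as a molecules x scoring-functions
table produced by an external engine; this module never computes such
scores.  Given measured potencies, each column's induced ranking is graded
by normalized discounted cumulative gain with relevance = pIC50:

    DCG_p  = rel_1 + sum_{i=2..p} rel_i / log2(i)
    NDCG_p = DCG_p / IDCG_p

where IDCG is the DCG of the potency-ideal ordering.  NDCG of 1 means the
score ranks compounds exactly as their potency would.  Note the discount
divides by log2(i) with the i = 2 term undiscounted (log2(2) = 1), the
classical Jarvelin-Kekalainen form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIRECTIONS = ("higher_is_better", "lower_is_better")


class DegenerateRelevanceError(ValueError):
    pass


class SchemaError(KeyError):
    pass


@dataclass
class ScoreTable:
    """Per-molecule scores from named scoring functions, each with an
    explicit direction flag (mandatory: score conventions differ)."""

    data: pd.DataFrame  # index = molecule ids
    direction: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate molecule ids in score table")
        for col in self.data.columns:
            if self.direction.get(col) not in DIRECTIONS:
                raise ValueError(f"column {col!r} lacks a valid direction flag")

    @classmethod
    def from_csv(cls, path: str | Path, direction: dict[str, str]) -> "ScoreTable":
        return cls(data=pd.read_csv(path, index_col="id"), direction=direction)

    def ranking(self, column: str) -> list[str]:
        """Molecule ids ordered best-first in the column's direction; tied
        scores keep input (index) order, stated because DCG is
        order-sensitive."""
        if column not in self.data.columns:
            raise SchemaError(f"unknown score column {column!r}")
        s = self.data[column]
        ascending = self.direction[column] == "lower_is_better"
        return list(s.sort_values(ascending=ascending, kind="stable").index)


def pic50(ic50_um: float) -> float:
    """pIC50 = -log10(IC50 in mol/L) from a micromolar IC50."""
    if ic50_um <= 0:
        raise ValueError("IC50 must be > 0")
    return -math.log10(ic50_um * 1e-6)


def dcg(rels_in_rank_order: Sequence[float]) -> float:
    """Discounted cumulative gain of relevances already in rank order."""
    rels = list(rels_in_rank_order)
    if not rels:
        raise ValueError("empty relevance vector")
    return rels[0] + sum(r / math.log2(i) for i, r in enumerate(rels[2 - 1 :], start=2))


def ndcg(score_ranking: Sequence[str], rels: Mapping[str, float]) -> float:
    """NDCG of a ranking against per-id relevances (pIC50, nonnegative).

    The ideal ordering sorts relevances descending, ties broken by id so
    the denominator is deterministic.  Equals 1 exactly when the ranking
    is relevance-sorted, up to ties and up to the order of the top two
    items: the classical discount gives ranks 1 and 2 the same weight
    (rel_2 is divided by log2(2) = 1), so exchanging them cannot change
    the DCG.
    """
    ranked = [rels[i] for i in score_ranking]
    if any(r < 0 for r in ranked):
        raise ValueError("relevances must be nonnegative")
    if all(r == 0 for r in ranked):
        raise DegenerateRelevanceError("all relevances zero: NDCG undefined")
    ideal = [rels[i] for i in sorted(score_ranking, key=lambda i: (-rels[i], i))]
    return dcg(ranked) / dcg(ideal)


def select_scoring_function(
    table: ScoreTable, ic50s: Mapping[str, float]
) -> tuple[str, dict[str, float]]:
    """Pick the score column whose ranking best matches measured potency.

    Molecules missing a score in any column are excluded (logged); each
    column's NDCG is computed over the common covered set with relevance
    pIC50.  Ties go to the first column in table order.
    """
    ids = [i for i in table.data.index if i in ic50s]
    complete = [i for i in ids if not table.data.loc[i].isna().any()]
    dropped = set(ids) - set(complete)
    if dropped:
        logger.warning("select_scoring_function: excluding %d molecules with missing scores: %s",
                       len(dropped), sorted(dropped)[:5])
    if len(complete) < 2:
        raise ValueError("need at least two molecules with IC50 and full score coverage")
    rels = {i: pic50(ic50s[i]) for i in complete}
    sub = ScoreTable(data=table.data.loc[complete], direction=table.direction)
    per_column = {col: ndcg(sub.ranking(col), rels) for col in table.data.columns}
    best = max(table.data.columns, key=lambda c: per_column[c])  # first-wins on ties
    return best, per_column


def threshold_stage(table: ScoreTable, column: str, cutoff: float) -> list[str]:
    """Ids passing the cutoff in the column's direction, boundary inclusive."""
    if column not in table.data.columns:
        raise SchemaError(f"unknown score column {column!r}")
    s = table.data[column]
    if table.direction[column] == "higher_is_better":
        mask = s >= cutoff
    else:
        mask = s <= cutoff
    return list(s.index[mask])


def calibrate_cutoff(
    table: ScoreTable,
    column: str,
    labels: Mapping[str, bool],
    objective: str = "max_EF",
    target_yield: float | None = None,
) -> float:
    """Scan unique score values for the cutoff optimizing an objective.

    ``max_EF`` maximizes the enrichment factor of the survivor set,
    ``max_youden`` maximizes sensitivity + specificity - 1, and
    ``target_yield`` returns the strictest cutoff whose yield still meets
    ``target_yield``.  Objective ties resolve to the more permissive
    cutoff (larger survivor set).
    """
    if objective not in ("max_EF", "max_youden", "target_yield"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "target_yield" and target_yield is None:
        raise ValueError("target_yield objective needs a target_yield value")
    ids = [i for i in table.data.index if i in labels]
    y = np.array([labels[i] for i in ids], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    P, N = int(y.sum()), int((~y).sum())
    base = P / (P + N)

    candidates = []
    for cutoff in sorted(set(table.data.loc[ids, column])):
        surv = set(threshold_stage(ScoreTable(table.data.loc[ids], table.direction), column, cutoff))
        pred = np.array([i in surv for i in ids])
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        yield_frac = tp / P
        sp = (N - fp) / N
        ef = ((tp / (tp + fp)) / base) if tp + fp else -math.inf
        n_surv = len(surv)
        if objective == "max_EF":
            score = ef
        elif objective == "max_youden":
            score = yield_frac + sp - 1.0
        else:
            score = None
        candidates.append((cutoff, score, yield_frac, n_surv))

    if objective == "target_yield":
        ok = [c for c in candidates if c[2] >= target_yield]
        if not ok:
            raise ValueError(f"no cutoff reaches yield {target_yield}")
        # strictest cutoff still meeting the target = smallest survivor set
        return min(ok, key=lambda c: (c[3], c[0]))[0]
    # ties -> more permissive (largest survivor set)
    return max(candidates, key=lambda c: (c[1], c[3]))[0]
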