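"""GA-wrapped descriptor selection and RBF-SVM classification.

The wrapper encodes a descriptor subset as a bitstring chromosome and
evolves a population whose fitness is the stratified k-fold
cross-validated accuracy of an RBF support-vector machine trained on the
selected columns.  Ties in fitness are broken toward fewer descriptors, a
mild parsimony pressure that mirrors the steep dimensionality reductions
such wrappers achieve in practice.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cascade import ConfusionCounts
from .descriptors import DescriptorTable, SchemaError

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """Labels contain a single class; classification is undefined."""


@dataclass(frozen=True)
class SvmParams:
    """RBF-SVM hyperparameters: C is the misclassification penalty, gamma
    the kernel width; both dimensionless and strictly positive."""

    C: float = 8.0
    gamma: float = 0.01
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")


@dataclass(frozen=True)
class GaConfig:
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # None -> 1/chromosome_length
    elitism: int = 1
    cv_folds: int = 10
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0 <= self.crossover_rate <= 1):
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class DescriptorSubset:
    names: tuple[str, ...]
    fitness: float

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("descriptor subset must be nonempty")


def _check_inputs(table: DescriptorTable, labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    if table.state != "normalized":
        raise ValueError("table must be normalized before SVM work")
    y = np.asarray(labels)
    if len(y) != len(table.data):
        raise ValueError("labels length does not match table rows")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels must contain both classes")
    return table.data.to_numpy(dtype=float), y


def _cv_accuracy(X: np.ndarray, y: np.ndarray, params: SvmParams, folds: int, seed: int) -> float:
    """Mean out-of-fold accuracy of a stratified k-fold split under seed."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(C=params.C, gamma=params.gamma, kernel=params.kernel)
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def ga_select(
    table: DescriptorTable,
    labels: Sequence[int],
    cfg: GaConfig | None = None,
    params: SvmParams | None = None,
) -> DescriptorSubset:
    """Evolve a descriptor subset maximizing cross-validated SVM accuracy.

    The initial population contains the all-columns chromosome, so the
    winner is never worse (on the shared fold assignment) than using every
    descriptor.  Fully reproducible under ``cfg.seed``; fitness evaluations
    are cached per chromosome.
    """
    cfg = cfg or GaConfig()
    params = params or SvmParams()
    X, y = _check_inputs(table, labels)
    n = X.shape[1]
    cols = table.columns
    rng = np.random.default_rng(cfg.seed)
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        if not chrom.any():
            return 0.0
        key = chrom.tobytes()
        if key not in cache:
            cache[key] = _cv_accuracy(X[:, chrom], y, params, cfg.cv_folds, cfg.seed)
        return cache[key]

    def rank_key(chrom: np.ndarray) -> tuple[float, int]:
        # higher fitness first; fewer descriptors wins ties
        return (fitness(chrom), -int(chrom.sum()))

    pop = [rng.random(n) < 0.5 for _ in range(cfg.population - 1)]
    pop = [p if p.any() else ~p for p in pop]
    pop.append(np.ones(n, dtype=bool))

    for _ in range(cfg.generations):
        pop.sort(key=rank_key, reverse=True)
        nxt = [pop[i].copy() for i in range(cfg.elitism)]
        while len(nxt) < cfg.population:
            parents = []
            for _ in range(2):  # tournament selection
                idx = rng.integers(0, cfg.population, size=cfg.tournament_size)
                parents.append(max((pop[i] for i in idx), key=rank_key))
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < cfg.crossover_rate and n > 1:
                cut = int(rng.integers(1, n))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(n) < mut_rate
                child[flip] = ~child[flip]
                if not child.any():
                    child[rng.integers(0, n)] = True
                if len(nxt) < cfg.population:
                    nxt.append(child)
        pop = nxt

    best = max(pop, key=rank_key)
    names = tuple(c for c, bit in zip(cols, best) if bit)
    return DescriptorSubset(names=names, fitness=fitness(best))


def grid_search(
    table: DescriptorTable,
    labels: Sequence[int],
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> SvmParams:
    """Exhaustive (C, gamma) search by mean CV accuracy.

    Ties are broken toward smaller C then smaller gamma (the least complex
    model among equals).  Default grids: C in 2^-2..2^6, gamma in 1e-3..1
    log-spaced.
    """
    C_grid = list(C_grid) if C_grid is not None else [2.0**k for k in range(-2, 7)]
    gamma_grid = list(gamma_grid) if gamma_grid is not None else list(np.logspace(-3, 0, 7))
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be nonempty")
    X, y = _check_inputs(table, labels)
    best: tuple[float, float, float] | None = None  # (-acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            acc = _cv_accuracy(X, y, SvmParams(C=C, gamma=gamma), folds, seed)
            cand = (-acc, C, gamma)
            if best is None or cand < best:
                best = cand
    return SvmParams(C=best[1], gamma=best[2])


@dataclass
class TrainedClassifier:
    """A fitted SVM restricted to a descriptor subset, bundled with the
    training scaling so new libraries can be projected before prediction."""

    subset: DescriptorSubset
    params: SvmParams
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    _svc: SVC | None = None

    def predict(self, table: DescriptorTable) -> np.ndarray:
        missing = [c for c in self.subset.names if c not in table.data.columns]
        if missing:
            raise SchemaError(f"table lacks subset columns: {missing}")
        X = table.data[list(self.subset.names)].to_numpy(dtype=float)
        return self._svc.predict(X)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError("not a TrainedClassifier archive")
        return obj


def train_svm(
    table: DescriptorTable,
    labels: Sequence[int],
    subset: DescriptorSubset,
    params: SvmParams | None = None,
) -> TrainedClassifier:
    params = params or SvmParams()
    _check_inputs(table, labels)
    missing = [c for c in subset.names if c not in table.data.columns]
    if missing:
        raise SchemaError(f"table lacks subset columns: {missing}")
    X = table.data[list(subset.names)].to_numpy(dtype=float)
    svc = SVC(C=params.C, gamma=params.gamma, kernel=params.kernel, random_state=0)
    svc.fit(X, np.asarray(labels))
    return TrainedClassifier(subset=subset, params=params, scaling=dict(table.scaling), _svc=svc)


def cross_validate(
    table: DescriptorTable,
    labels: Sequence[int],
    subset: DescriptorSubset,
    params: SvmParams | None = None,
    folds: int = 10,
    seed: int = 0,
) -> ConfusionCounts:
    """Pooled out-of-fold confusion counts under seeded stratified folds.

    Counts are pooled (not averaged) across folds, so TP+FN equals the
    number of positives and TN+FP the number of negatives.
    """
    params = params or SvmParams()
    X, y = _check_inputs(table, labels)
    cols = [table.columns.index(c) for c in subset.names]
    X = X[:, cols]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(C=params.C, gamma=params.gamma, kernel=params.kernel)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        fn += int(((pred != 1) & (truth == 1)).sum())
        tn += int(((pred != 1) & (truth != 1)).sum())
        fp += int(((pred == 1) & (truth != 1)).sum())
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)
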