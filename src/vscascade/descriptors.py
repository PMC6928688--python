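"""Molecular descriptor computation and preprocessing.

A descriptor table goes through three states: ``raw`` (as computed by a
backend), ``filtered`` (after the three redundancy rules: null/constant
columns, near-zero spread, high pairwise correlation) and ``normalized``
(min-max scaled to [0, 1] with the scaling retained so screening libraries
can be projected into the training domain).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors

from .dataset import MoleculeRecord

logger = logging.getLogger(__name__)


class SchemaError(KeyError):
    pass


class DescriptorBackend(Protocol):
    """Contract for a named-descriptor provider."""

    @property
    def names(self) -> list[str]: ...

    def compute(self, mol: Chem.Mol) -> list[float]:
        """Descriptor values aligned with :attr:`names`; may raise."""


class RDKitDescriptorBackend:
    """The standard RDKit 2D descriptor set (~210 descriptors)."""

    def __init__(self) -> None:
        self._names = [name for name, _ in RDDescriptors._descList]

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def compute(self, mol: Chem.Mol) -> list[float]:
        values = RDDescriptors.CalcMolDescriptors(mol, missingVal=np.nan)
        return [float(values[n]) for n in self._names]


@dataclass
class DescriptorTable:
    """Molecules x named numeric descriptors with preprocessing state."""

    data: pd.DataFrame  # index = molecule ids, columns = descriptor names
    state: str = "raw"  # raw | filtered | normalized
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate molecule ids in descriptor table")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path, state: str = "raw") -> "DescriptorTable":
        return cls(data=pd.read_csv(path, index_col="id"), state=state)


@dataclass
class FilterReport:
    """Accounting of the redundancy filter: every input column appears in
    exactly one of the dropped sets or the retained set."""

    dropped_null: list[str]
    dropped_lowvar: list[str]
    dropped_correlated: list[tuple[str, str]]  # (dropped, partner that triggered it)
    retained: list[str]
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=list))


def compute_descriptors(
    molecules: Sequence[MoleculeRecord], backend: DescriptorBackend | None = None
) -> DescriptorTable:
    """One row per parsable molecule; a backend failure leaves that row's
    entries missing (NaN) rather than aborting the table."""
    backend = backend or RDKitDescriptorBackend()
    names = backend.names
    rows, ids = [], []
    for rec in molecules:
        if rec.structure is None:
            logger.warning("compute_descriptors: omitting unparsable molecule %s", rec.id)
            continue
        try:
            values = backend.compute(rec.structure)
        except Exception:  # backend failure -> missing row, not fatal
            logger.warning("compute_descriptors: backend failed on %s", rec.id, exc_info=True)
            values = [np.nan] * len(names)
        ids.append(rec.id)
        rows.append(values)
    data = pd.DataFrame(rows, index=ids, columns=names, dtype=float)
    return DescriptorTable(data=data, state="raw", metadata={"backend": type(backend).__name__, "n_descriptors": len(names)})


def filter_descriptors(
    table: DescriptorTable,
    null_frac_max: float = 0.05,
    stdev_min: float = 0.005,
    corr_max: float = 0.95,
) -> tuple[DescriptorTable, FilterReport]:
    """Apply the three redundancy rules, in order.

    (i)   drop columns that are mostly missing (> ``null_frac_max``),
          constant, or all-zero;
    (ii)  drop columns whose coefficient of variation (sd / |mean|) is
          below ``stdev_min`` -- a near-constant relative spread; columns
          with |mean| ~ 0 are kept, since relative spread is then
          ill-defined and rule (i) already caught true constants;
    (iii) drop columns with pairwise |Pearson r| > ``corr_max``; columns
          are scanned in input order and the *later* member of an offending
          pair is dropped, which makes the outcome deterministic.

    Remaining missing entries are imputed with the column median so labelled
    rows are never lost.
    """
    if table.state != "raw":
        raise ValueError(f"filter_descriptors expects a raw table, got {table.state}")
    df = table.data
    if df.empty:
        raise ValueError("empty descriptor table")

    dropped_null, dropped_lowvar, dropped_corr = [], [], []

    # rule (i): null-heavy / constant / all-zero
    keep = []
    for col in df.columns:
        s = df[col]
        null_frac = s.isna().mean()
        nun = s.dropna().nunique()
        if null_frac > null_frac_max or nun <= 1 or (s.fillna(0) == 0).all() or not np.isfinite(s.dropna()).all():
            dropped_null.append(col)
        else:
            keep.append(col)
    df = df[keep]

    # rule (ii): coefficient of variation below threshold
    keep = []
    for col in df.columns:
        s = df[col].dropna()
        mean = abs(s.mean())
        if mean > 1e-12 and s.std(ddof=1) < stdev_min * mean:
            dropped_lowvar.append(col)
        else:
            keep.append(col)
    df = df[keep]

    # impute before the correlation scan so Pearson r is defined everywhere
    df = df.fillna(df.median())

    # rule (iii): high pairwise correlation, later column dropped
    corr = df.corr().abs().to_numpy()
    cols = list(df.columns)
    alive = [True] * len(cols)
    for i in range(len(cols)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(cols)):
            if alive[j] and corr[i, j] > corr_max:
                alive[j] = False
                dropped_corr.append((cols[j], cols[i]))
    retained = [c for c, a in zip(cols, alive) if a]

    report = FilterReport(
        dropped_null=dropped_null,
        dropped_lowvar=dropped_lowvar,
        dropped_correlated=dropped_corr,
        retained=retained,
        params={
            "null_frac_max": null_frac_max,
            "stdev_min": stdev_min,
            "stdev_rule": "coefficient of variation: sd < stdev_min * |column mean|",
            "corr_max": corr_max,
        },
    )
    out = DescriptorTable(
        data=df[retained].copy(), state="filtered", metadata={**table.metadata, "filter": report.params}
    )
    return out, report


def normalize(table: DescriptorTable) -> DescriptorTable:
    """Min-max scale every column to [0, 1], storing per-column (min, max)."""
    if table.state != "filtered":
        raise ValueError(f"normalize expects a filtered table, got {table.state}")
    df = table.data
    scaling: dict[str, tuple[float, float]] = {}
    out = {}
    for col in df.columns:
        lo, hi = float(df[col].min()), float(df[col].max())
        if hi <= lo:
            raise ValueError(f"zero-range column {col!r} survived filtering")
        scaling[col] = (lo, hi)
        out[col] = (df[col] - lo) / (hi - lo)
    return DescriptorTable(
        data=pd.DataFrame(out, index=df.index), state="normalized",
        scaling=scaling, metadata=dict(table.metadata),
    )


def apply_scaling(table: DescriptorTable, scaling: dict[str, tuple[float, float]]) -> DescriptorTable:
    """Project a new table through stored training scaling.

    Values outside the training range are clipped to [0, 1] so the SVM never
    sees inputs outside its training domain; columns absent from the scaling
    are dropped.
    """
    missing = [c for c in scaling if c not in table.data.columns]
    if missing:
        raise SchemaError(f"table lacks scaled columns: {missing}")
    out = {}
    for col, (lo, hi) in scaling.items():
        out[col] = ((table.data[col] - lo) / (hi - lo)).clip(0.0, 1.0)
    return DescriptorTable(
        data=pd.DataFrame(out, index=table.data.index), state="normalized",
        scaling=dict(scaling), metadata=dict(table.metadata),
    )


def save_scaling(scaling: dict[str, tuple[float, float]], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: list(v) for k, v in scaling.items()}, indent=2))


def load_scaling(path: str | Path) -> dict[str, tuple[float, float]]:
    raw = json.loads(Path(path).read_text())
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
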