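"""Labelled actives/decoys dataset construction.

Builds the training material for a ligand-based screening campaign:
activity-cutoff labelling of IC50-annotated molecules, circular-fingerprint
Tanimoto similarity, property-matched decoy selection (topologically
dissimilar, physically similar presumed-inactives) and reproducible
train/test/validation splits.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

LABELS = ("active", "inactive", "decoy", "unlabeled")

# ECFP4 convention: circular fingerprint, radius 2, folded to 2048 bits.
FP_RADIUS = 2
FP_NBITS = 2048


class MalformedRecordError(ValueError):
    """A molecule record violates a field invariant (e.g. negative IC50)."""


class SizingError(ValueError):
    """A split request exceeds the available record pool."""


@dataclass
class MoleculeRecord:
    """One library compound.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    structure : rdkit.Chem.Mol or None
        Connection-table molecule; ``None`` marks an unparsable record.
    ic50 : float or None
        Measured IC50 in micromolar, when known.
    label : str
        One of ``active``, ``inactive``, ``decoy``, ``unlabeled``.
    """

    id: str
    structure: Chem.Mol | None = None
    ic50: float | None = None
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} for record {self.id}")
        if self.ic50 is not None and self.ic50 < 0:
            raise MalformedRecordError(f"record {self.id}: negative ic50 {self.ic50}")

    @property
    def smiles(self) -> str | None:
        return Chem.MolToSmiles(self.structure) if self.structure is not None else None


@dataclass(frozen=True)
class FingerprintBits:
    """Sparse on-bit set of a folded circular fingerprint."""

    bits: frozenset[int]

    @classmethod
    def from_mol(cls, mol: Chem.Mol, radius: int = FP_RADIUS, n_bits: int = FP_NBITS) -> "FingerprintBits":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        fp = gen.GetFingerprint(mol)
        return cls(bits=frozenset(fp.GetOnBits()))


@dataclass(frozen=True)
class PropertyWindow:
    """Half-width tolerances for five-property decoy matching.

    Defaults follow the published defaults of the decoy-finding tool the
    construction mirrors: MW +/-40 Da, donors +/-1, acceptors +/-2,
    rotatable bonds +/-1, logP +/-1.0.
    """

    mw_tol: float = 40.0
    hbd_tol: int = 1
    hba_tol: int = 2
    rotb_tol: int = 1
    logp_tol: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mw_tol", "hbd_tol", "hba_tol", "rotb_tol", "logp_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DatasetSplit:
    training: list[MoleculeRecord] = field(default_factory=list)
    test: list[MoleculeRecord] = field(default_factory=list)
    validation: list[MoleculeRecord] = field(default_factory=list)


def mol_properties(mol: Chem.Mol) -> dict[str, float]:
    """The five matching properties: MW, HBD, HBA, rotatable bonds, logP."""
    return {
        "mw": Descriptors.MolWt(mol),
        "hbd": rdMolDescriptors.CalcNumHBD(mol),
        "hba": rdMolDescriptors.CalcNumHBA(mol),
        "rotb": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "logp": Crippen.MolLogP(mol),
    }


def properties_within(cand: dict[str, float], ref: dict[str, float], window: PropertyWindow) -> bool:
    return (
        abs(cand["mw"] - ref["mw"]) <= window.mw_tol
        and abs(cand["hbd"] - ref["hbd"]) <= window.hbd_tol
        and abs(cand["hba"] - ref["hba"]) <= window.hba_tol
        and abs(cand["rotb"] - ref["rotb"]) <= window.rotb_tol
        and abs(cand["logp"] - ref["logp"]) <= window.logp_tol
    )


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b|.

    Two empty fingerprints (degenerate structures) give 0 by convention.
    """
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def deduplicate(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """Drop records with a duplicate canonical SMILES; first occurrence wins."""
    seen: set[str] = set()
    out = []
    for rec in records:
        key = rec.smiles if rec.structure is not None else f"__id__{rec.id}"
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def label_by_activity(
    records: Sequence[MoleculeRecord], pos_cutoff: float = 10.0, neg_cutoff: float = 100.0
) -> list[MoleculeRecord]:
    """Label records by IC50 cutoffs (micromolar), both boundaries inclusive.

    IC50 <= ``pos_cutoff`` -> active; IC50 >= ``neg_cutoff`` -> inactive;
    strictly between the cutoffs -> dropped (the gray zone guards against
    borderline actives contaminating the negative class); missing IC50 ->
    retained unlabeled.
    """
    if not pos_cutoff < neg_cutoff:
        raise ValueError("pos_cutoff must be < neg_cutoff")
    out = []
    for rec in records:
        if rec.ic50 is None:
            out.append(replace(rec, label="unlabeled"))
        elif rec.ic50 < 0:
            raise MalformedRecordError(f"record {rec.id}: negative ic50 {rec.ic50}")
        elif rec.ic50 <= pos_cutoff:
            out.append(replace(rec, label="active"))
        elif rec.ic50 >= neg_cutoff:
            out.append(replace(rec, label="inactive"))
        # gray zone: excluded
    return out


def find_decoys(
    actives: Sequence[MoleculeRecord],
    candidates: Sequence[MoleculeRecord],
    tc_max: float = 0.5,
    window: PropertyWindow | None = None,
    max_per_active: int = 36,
) -> list[MoleculeRecord]:
    """Select property-matched, topologically dissimilar decoys.

    A candidate qualifies when its circular-fingerprint Tanimoto to *every*
    active is strictly below ``tc_max`` and its five physical properties all
    fall within ``window`` of *at least one* active.  Accepted decoys are
    capped at ``max_per_active`` per matched active (a candidate counts
    against the first active, in input order, whose window it satisfies) and
    returned sorted by candidate id.
    """
    if not actives:
        raise ValueError("actives must be nonempty")
    if not (0 < tc_max <= 1):
        raise ValueError("tc_max must lie in (0, 1]")
    window = window or PropertyWindow()

    active_fps = [FingerprintBits.from_mol(a.structure) for a in actives]
    active_props = [mol_properties(a.structure) for a in actives]

    per_active_count = [0] * len(actives)
    accepted: list[MoleculeRecord] = []
    for cand in sorted(candidates, key=lambda r: r.id):
        if cand.structure is None:
            logger.warning("find_decoys: skipping unparsable candidate %s", cand.id)
            continue
        fp = FingerprintBits.from_mol(cand.structure)
        if any(tanimoto(fp, afp) >= tc_max for afp in active_fps):
            continue
        props = mol_properties(cand.structure)
        matched = next(
            (i for i, ap in enumerate(active_props) if properties_within(props, ap, window)),
            None,
        )
        if matched is None or per_active_count[matched] >= max_per_active:
            continue
        per_active_count[matched] += 1
        accepted.append(replace(cand, label="decoy"))
    return accepted


def make_splits(
    actives: Sequence[MoleculeRecord],
    decoys: Sequence[MoleculeRecord],
    inactives: Sequence[MoleculeRecord] = (),
    spec: dict[str, dict[str, int]] | None = None,
    seed: int = 0,
) -> DatasetSplit:
    """Draw disjoint training/test/validation splits with exact composition.

    ``spec`` maps split name -> {"actives": n, "decoys": n, "inactives": n}
    (missing keys mean 0; a count of -1 means "all remaining").  Sampling is
    without replacement under ``seed`` so a fixed seed reproduces the split.
    """
    spec = spec or {}
    rng = random.Random(seed)
    pools = {
        "actives": sorted(actives, key=lambda r: r.id),
        "decoys": sorted(decoys, key=lambda r: r.id),
        "inactives": sorted(inactives, key=lambda r: r.id),
    }
    for pool in pools.values():
        rng.shuffle(pool)
    cursors = {k: 0 for k in pools}

    def draw(pool_name: str, n: int) -> list[MoleculeRecord]:
        pool, start = pools[pool_name], cursors[pool_name]
        avail = len(pool) - start
        if n == -1:
            n = avail
        if n > avail:
            raise SizingError(
                f"requested {n} {pool_name} but only {avail} remain (short by {n - avail})"
            )
        cursors[pool_name] = start + n
        return pool[start : start + n]

    split = DatasetSplit()
    for name in ("training", "test", "validation"):
        want = spec.get(name, {})
        members: list[MoleculeRecord] = []
        for pool_name in ("actives", "decoys", "inactives"):
            members.extend(draw(pool_name, want.get(pool_name, 0)))
        setattr(split, name, members)
    return split


# ---------------------------------------------------------------------------
# File I/O: tab-separated SMILES with optional IC50, split manifests
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Read `SMILES<TAB>id[<TAB>ic50_uM]` lines; unparsable structures kept
    with ``structure=None`` so downstream stages can log and skip them."""
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smi, mol_id = parts[0], (parts[1] if len(parts) > 1 else f"line{ln}")
        ic50 = float(parts[2]) if len(parts) > 2 and parts[2] else None
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("read_smiles_file: unparsable SMILES at line %d (%s)", ln, mol_id)
        records.append(MoleculeRecord(id=mol_id, structure=mol, ic50=ic50))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    lines = []
    for rec in records:
        if rec.structure is None:
            continue
        ic50 = "" if rec.ic50 is None else f"\t{rec.ic50:g}"
        lines.append(f"{rec.smiles}\t{rec.id}{ic50}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_split_manifest(split: DatasetSplit, out_dir: str | Path, metadata: dict | None = None) -> None:
    """Write `id,split,label` manifest, per-split SMILES and JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["id,split,label"]
    for name in ("training", "test", "validation"):
        members = getattr(split, name)
        rows.extend(f"{r.id},{name},{r.label}" for r in members)
        if members:
            write_smiles_file(members, out / f"{name}.smi")
    (out / "manifest.csv").write_text("\n".join(rows) + "\n")
    meta = {"fingerprint": {"kind": "morgan", "radius": FP_RADIUS, "n_bits": FP_NBITS}}
    meta.update(metadata or {})
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
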