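"""Pharmacophore queries and ligand matching.

A query is a set of typed feature spheres (donor, acceptor, aromatic,
hydrophobic, cation, anion) with optional excluded volumes carved from the
receptor.  A ligand conformer matches when some rigid placement puts a
same-typed ligand feature inside every required sphere without pushing any
ligand atom into an excluded volume.  Matching is purely rigid: conformer
flexibility is handled by testing several pre-generated conformers.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("donor", "acceptor", "aromatic", "hydrophobic", "cation", "anion")

# SMARTS typing rules: deliberately small and auditable, element-based where
# possible.  They capture the toy chemistry of this package's fixtures and
# common functional groups, not a full pharmacophore perception model.
_DONOR_SMARTS = Chem.MolFromSmarts("[#7!H0,#8!H0]")
_ACCEPTOR_SMARTS = Chem.MolFromSmarts(
    "[$([#8;!$([#8X2H0]([#6])[#6X3]=O)]),$([#7;X1,X2,X3;!+1;!$([#7X3][#6X3]=O)])]"
)
_CATION_SMARTS = Chem.MolFromSmarts("[+1,+2,$([NX3;H2;$(N[CX4]);!$(NC=O)])]")
_ANION_SMARTS = Chem.MolFromSmarts("[-1,-2,$([OX2H1][CX3]=O)]")


@dataclass(frozen=True)
class Feature:
    type: str
    centroid: tuple[float, float, float]
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be > 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass(frozen=True)
class ExcludedVolume:
    centroid: tuple[float, float, float]
    radius: float

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass
class PharmacophoreQuery:
    features: list[Feature]
    excluded_volumes: list[ExcludedVolume] = field(default_factory=list)
    coverage_band: tuple[float, float] = (0.25, 0.75)
    name: str = "query"

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("query must carry at least one feature")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "coverage_band": list(self.coverage_band),
            "features": [
                {"type": f.type, "centroid": list(f.centroid), "radius": f.radius}
                for f in self.features
            ],
            "excluded_volumes": [
                {"centroid": list(v.centroid), "radius": v.radius} for v in self.excluded_volumes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PharmacophoreQuery":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d.get("name", "query"),
            coverage_band=tuple(d.get("coverage_band", (0.25, 0.75))),
            features=[Feature(f["type"], tuple(f["centroid"]), f["radius"]) for f in d["features"]],
            excluded_volumes=[ExcludedVolume(tuple(v["centroid"]), v["radius"]) for v in d["excluded_volumes"]],
        )


@dataclass
class LigandFeatureSet:
    """Typed feature points of one ligand conformer, plus its heavy-atom
    coordinates (used for excluded-volume clash checks; may be empty for
    synthetic feature sets)."""

    mol_id: str
    conformer: int
    features: list[Feature]
    atom_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares rigid superposition of paired points.

    Returns (rotation, translation, rmsd) such that mobile @ R.T + t best
    fits reference.  Handles the degenerate 1- and 2-point cases (the
    rotation is then only determined up to the unresolved degrees of
    freedom, which is irrelevant for distance checks).
    """
    mobile = np.atleast_2d(np.asarray(mobile, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have equal shape")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def extract_ligand_features(
    mol: Chem.Mol | str,
    mol_id: str = "mol",
    conformers: int = 10,
    seed: int = 0,
) -> list[LigandFeatureSet]:
    """Typed 3D feature points for seeded ETKDG conformers of a molecule.

    Feature typing: H-bearing N/O -> donor; lone-pair N/O -> acceptor;
    aromatic-ring centroid -> aromatic; aliphatic carbon with >= 2 carbon
    neighbours and no heteroatom neighbour -> hydrophobic; formal positive
    charge or protonatable primary amine -> cation; formal negative charge
    or carboxylic acid (group centroid) -> anion.  Embedding failures are
    logged and yield an empty list.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            logger.warning("extract_ligand_features: unparsable SMILES for %s", mol_id)
            return []
        mol = parsed
    if conformers < 1:
        raise ValueError("conformers must be >= 1")

    typed_atoms: dict[str, list[tuple[int, ...]]] = {
        "donor": [m for m in mol.GetSubstructMatches(_DONOR_SMARTS)],
        "acceptor": [m for m in mol.GetSubstructMatches(_ACCEPTOR_SMARTS)],
        "cation": [m for m in mol.GetSubstructMatches(_CATION_SMARTS)],
    }
    anion_groups = [m for m in mol.GetSubstructMatches(Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-]"))]
    charged_neg = [(a.GetIdx(),) for a in mol.GetAtoms()
                   if a.GetFormalCharge() < 0 and not any(a.GetIdx() in g for g in anion_groups)]
    hydrophobic = []
    for a in mol.GetAtoms():
        if a.GetSymbol() != "C" or a.GetIsAromatic():
            continue
        nbrs = [n.GetSymbol() for n in a.GetNeighbors()]
        if nbrs.count("C") >= 2 and all(s == "C" for s in nbrs):
            hydrophobic.append((a.GetIdx(),))
    aromatic_rings = [r for r in mol.GetRingInfo().AtomRings()
                      if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)]

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31)
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=conformers, params=params)
    if not conf_ids:
        logger.warning("extract_ligand_features: embedding failed for %s", mol_id)
        return []

    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    out = []
    for cid in conf_ids:
        pos = molh.GetConformer(cid).GetPositions()

        def centroid(idx: tuple[int, ...]) -> tuple[float, float, float]:
            return tuple(pos[list(idx)].mean(axis=0))

        feats: list[Feature] = []
        for ftype in ("donor", "acceptor", "cation"):
            feats.extend(Feature(ftype, centroid(m)) for m in typed_atoms[ftype])
        feats.extend(Feature("anion", centroid(m)) for m in anion_groups + charged_neg)
        feats.extend(Feature("hydrophobic", centroid(m)) for m in hydrophobic)
        feats.extend(Feature("aromatic", centroid(r)) for r in aromatic_rings)
        out.append(LigandFeatureSet(mol_id=mol_id, conformer=int(cid), features=feats,
                                    atom_coords=pos[heavy]))
    return out


@dataclass(frozen=True)
class MatchPolicy:
    """``required`` = "all" demands every query feature be satisfied;
    "n_minus_1" tolerates one unmatched feature (for queries with >= 2)."""

    required: str = "all"
    max_assignments: int = 200_000

    def n_required(self, n_features: int) -> int:
        if self.required == "all":
            return n_features
        if self.required == "n_minus_1":
            return max(1, n_features - 1)
        raise ValueError(f"unknown policy {self.required!r}")


def _violates_excluded(coords: np.ndarray, volumes: Sequence[ExcludedVolume]) -> bool:
    if len(coords) == 0:
        return False
    for v in volumes:
        if (np.linalg.norm(coords - v.xyz, axis=1) < v.radius).any():
            return True
    return False


def match_ligand(
    query: PharmacophoreQuery,
    feats: LigandFeatureSet,
    policy: MatchPolicy | None = None,
) -> tuple[bool, float]:
    """Exhaustive rigid match of a ligand feature set against a query.

    Every injective assignment of required query features to same-typed
    ligand features is tried; each is scored by Kabsch superposition of
    the ligand onto the query frame.  A placement succeeds when every
    assigned feature lands within its sphere radius and no ligand atom
    penetrates an excluded volume.  Returns (matched, best alignment RMSD);
    an unmatchable ligand gives (False, inf).
    """
    policy = policy or MatchPolicy()
    if not feats.features:
        return False, math.inf
    need = policy.n_required(len(query.features))

    by_type: dict[str, list[Feature]] = {}
    for f in feats.features:
        by_type.setdefault(f.type, []).append(f)

    best_rmsd = math.inf
    matched = False
    n_tried = 0
    for subset in itertools.combinations(range(len(query.features)), need):
        qfeats = [query.features[i] for i in subset]
        cand_lists = [by_type.get(q.type, []) for q in qfeats]
        if any(not c for c in cand_lists):
            continue
        for assignment in itertools.product(*cand_lists):
            if len({id(f) for f in assignment}) < len(assignment):
                continue  # injective only
            n_tried += 1
            if n_tried > policy.max_assignments:
                logger.warning("match_ligand: assignment budget exhausted for %s", feats.mol_id)
                return matched, best_rmsd
            lig_pts = np.array([f.xyz for f in assignment])
            q_pts = np.array([q.xyz for q in qfeats])
            R, t, rmsd = superpose(lig_pts, q_pts)
            moved = lig_pts @ R.T + t
            dists = np.linalg.norm(moved - q_pts, axis=1)
            if (dists <= np.array([q.radius for q in qfeats])).all():
                atoms = feats.atom_coords @ R.T + t if len(feats.atom_coords) else feats.atom_coords
                if not _violates_excluded(atoms, query.excluded_volumes):
                    matched = True
                    best_rmsd = min(best_rmsd, rmsd)
    return matched, best_rmsd


def match_any_conformer(
    query: PharmacophoreQuery,
    conformer_feats: Sequence[LigandFeatureSet],
    policy: MatchPolicy | None = None,
) -> tuple[bool, float]:
    """Best match over a molecule's conformer feature sets."""
    best = (False, math.inf)
    for fs in conformer_feats:
        ok, rmsd = match_ligand(query, fs, policy)
        if ok and rmsd < best[1]:
            best = (True, rmsd)
    return best
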