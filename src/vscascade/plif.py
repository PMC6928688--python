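"""Protein-ligand interaction fingerprints (PLIF).

Given a set of ligand-receptor complexes superposed into a common frame,
contacts between ligand atoms and receptor residues are detected with
geometric rules, summarized per (residue, interaction kind) into a
bit matrix, and the per-column contact frequencies drive pharmacophore
query generation: a residue touched by most of the known inhibitors (say
17 of 18 complexes, 94.4%) becomes an anchoring feature at the mean
position of the ligand atoms that made the contact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .pharmacophore import ExcludedVolume, Feature, PharmacophoreQuery, superpose

logger = logging.getLogger(__name__)

CONTACT_KINDS = ("hbond_donor", "hbond_acceptor", "ionic", "hydrophobic")

# Receptor atom roles by (residue name, atom name); backbone N donates and
# backbone O accepts for every residue.
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"), ("CYS", "SG"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}
_CATIONIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
_ANIONIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


class AtomTypingError(ValueError):
    pass


@dataclass(frozen=True)
class ReceptorAtom:
    chain: str
    res_number: int
    res_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def residue(self) -> tuple[str, int, str]:
        return (self.chain, self.res_number, self.res_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class LigandAtom:
    index: int
    element: str
    coord: tuple[float, float, float]
    charge: int = 0
    n_hydrogens: int = 1  # bare PDB ligands lack H records; assume protonated N/O

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Complex3D:
    """One aligned ligand-receptor complex (coordinates in Angstrom,
    residues addressed by author numbering)."""

    receptor_atoms: list[ReceptorAtom]
    ligand_atoms: list[LigandAtom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("complex has an empty ligand")
        coords = [a.coord for a in self.receptor_atoms] + [a.coord for a in self.ligand_atoms]
        if not np.isfinite(np.asarray(coords, dtype=float)).all():
            raise ValueError("non-finite coordinates in complex")
        for a in list(self.receptor_atoms) + list(self.ligand_atoms):
            if not a.element:
                raise AtomTypingError(f"atom without element type: {a}")

    @property
    def id(self) -> str:
        return str(self.metadata.get("id", "complex"))


@dataclass(frozen=True)
class ContactRules:
    """Geometric contact criteria and the pseudo-energy model.

    A contact's pseudo-energy is depth x a linear falloff from the ideal
    distance to the cutoff, so it decreases monotonically as the geometry
    degrades; contacts weaker than ``weak_threshold`` are suppressed and
    ``strong_threshold`` marks the high-confidence tier.
    """

    hbond_dist_max: float = 3.5
    hbond_angle_min: float = 120.0  # degrees, antecedent-donor...acceptor
    hbond_dist_ideal: float = 2.8
    ionic_dist_max: float = 4.0
    ionic_dist_ideal: float = 3.0
    hydrophobic_dist_max: float = 4.5
    hydrophobic_dist_ideal: float = 3.8
    depth: dict = field(default_factory=lambda: {
        "hbond_donor": 2.5, "hbond_acceptor": 2.5, "ionic": 3.5, "hydrophobic": 1.2,
    })
    weak_threshold: float = 0.5
    strong_threshold: float = 1.5


@dataclass(frozen=True)
class ContactRecord:
    residue: tuple[str, int, str]
    kind: str
    pseudo_energy: float
    ligand_atom: int
    ligand_coord: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ligand_feature_type: str = "hydrophobic"

    def __post_init__(self) -> None:
        if self.kind not in CONTACT_KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.pseudo_energy < 0:
            raise ValueError("pseudo-energy must be >= 0")


def _falloff(dist: float, ideal: float, cutoff: float) -> float:
    if dist <= ideal:
        return 1.0
    if dist >= cutoff:
        return 0.0
    return (cutoff - dist) / (cutoff - ideal)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b, in degrees."""
    v1, v2 = a - b, c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _antecedent(atom: ReceptorAtom, residue_atoms: Sequence[ReceptorAtom]) -> ReceptorAtom | None:
    others = [a for a in residue_atoms if a.atom_name != atom.atom_name]
    if not others:
        return None
    return min(others, key=lambda a: float(np.linalg.norm(a.xyz - atom.xyz)))


def detect_contacts(complex: Complex3D, rules: ContactRules | None = None) -> list[ContactRecord]:
    """Detect residue-ligand contacts with geometric rules.

    Hydrogen bonds: donor/acceptor heavy atoms within ``hbond_dist_max``
    and, when the donor's bonded neighbour is known, an
    antecedent-donor...acceptor angle of at least ``hbond_angle_min``
    (bare ligand atoms carry no bonds, so ligand-donor angles pass by
    construction).  Ionic: opposite formal charges within
    ``ionic_dist_max``.  Hydrophobic: carbon-carbon within
    ``hydrophobic_dist_max``.  Contacts with pseudo-energy below the weak
    threshold are suppressed.
    """
    rules = rules or ContactRules()
    by_residue: dict[tuple[str, int, str], list[ReceptorAtom]] = {}
    for atom in complex.receptor_atoms:
        by_residue.setdefault(atom.residue, []).append(atom)

    contacts: list[ContactRecord] = []

    def emit(kind: str, residue, energy: float, lig: LigandAtom, lig_type: str) -> None:
        if energy >= rules.weak_threshold:
            contacts.append(ContactRecord(
                residue=residue, kind=kind, pseudo_energy=energy,
                ligand_atom=lig.index, ligand_coord=lig.coord, ligand_feature_type=lig_type,
            ))

    for residue, atoms in by_residue.items():
        for ratom in atoms:
            key = (ratom.res_name, ratom.atom_name)
            is_donor = ratom.atom_name == "N" or key in _SIDECHAIN_DONORS
            is_acceptor = ratom.atom_name == "O" or key in _SIDECHAIN_ACCEPTORS
            r_charge = 1 if key in _CATIONIC else (-1 if key in _ANIONIC else 0)
            for latom in complex.ligand_atoms:
                d = float(np.linalg.norm(ratom.xyz - latom.xyz))
                lig_polar = latom.element in ("N", "O", "S")
                # receptor donates -> ligand acceptor feature
                if is_donor and lig_polar and latom.charge == 0 and d <= rules.hbond_dist_max:
                    ante = _antecedent(ratom, atoms)
                    ok = ante is None or _angle(ante.xyz, ratom.xyz, latom.xyz) >= rules.hbond_angle_min
                    if ok:
                        e = rules.depth["hbond_donor"] * _falloff(d, rules.hbond_dist_ideal, rules.hbond_dist_max)
                        emit("hbond_donor", residue, e, latom, "acceptor")
                # receptor accepts -> ligand donor feature (needs an H on the ligand atom)
                if is_acceptor and lig_polar and latom.n_hydrogens > 0 and latom.charge == 0 and d <= rules.hbond_dist_max:
                    e = rules.depth["hbond_acceptor"] * _falloff(d, rules.hbond_dist_ideal, rules.hbond_dist_max)
                    emit("hbond_acceptor", residue, e, latom, "donor")
                if r_charge and latom.charge and r_charge * latom.charge < 0 and d <= rules.ionic_dist_max:
                    e = rules.depth["ionic"] * _falloff(d, rules.ionic_dist_ideal, rules.ionic_dist_max)
                    emit("ionic", residue, e, latom, "cation" if latom.charge > 0 else "anion")
                if ratom.element == "C" and latom.element == "C" and d <= rules.hydrophobic_dist_max:
                    e = rules.depth["hydrophobic"] * _falloff(d, rules.hydrophobic_dist_ideal, rules.hydrophobic_dist_max)
                    emit("hydrophobic", residue, e, latom, "hydrophobic")
    return contacts


@dataclass
class PlifMatrix:
    """Complexes x (residue, kind) interaction bits with frequencies."""

    bits: pd.DataFrame  # index = complex ids, columns = "chain:num:resname|kind"
    contacts: dict[str, list[ContactRecord]] = field(default_factory=dict)

    @property
    def frequencies(self) -> pd.Series:
        return self.bits.mean(axis=0)

    @staticmethod
    def column_key(residue: tuple[str, int, str], kind: str) -> str:
        chain, num, name = residue
        return f"{chain}:{num}:{name}|{kind}"


def build_plif(complexes: Sequence[Complex3D], rules: ContactRules | None = None) -> PlifMatrix:
    """One fingerprint row per complex; columns sorted by frequency
    (descending) for reporting.  Superposition into a common frame is the
    caller's duty (see :func:`superpose_complexes`)."""
    if not complexes:
        raise ValueError("empty complex list")
    rules = rules or ContactRules()
    rows: dict[str, dict[str, int]] = {}
    all_contacts: dict[str, list[ContactRecord]] = {}
    for cx in complexes:
        contacts = detect_contacts(cx, rules)
        all_contacts[cx.id] = contacts
        row: dict[str, int] = {}
        for c in contacts:
            row[PlifMatrix.column_key(c.residue, c.kind)] = 1
        rows[cx.id] = row
    all_cols = sorted({k for row in rows.values() for k in row})
    bits = pd.DataFrame(
        [[row.get(c, 0) for c in all_cols] for row in rows.values()],
        index=list(rows.keys()), columns=all_cols, dtype=int,
    )
    order = bits.mean(axis=0).sort_values(ascending=False, kind="stable").index
    return PlifMatrix(bits=bits[order], contacts=all_contacts)


def superpose_complexes(complexes: Sequence[Complex3D], reference: int = 0) -> list[Complex3D]:
    """RMSD-minimizing superposition helper onto one reference complex,
    pairing receptor atoms by (chain, residue, atom name)."""
    ref = complexes[reference]
    ref_map = {(a.residue, a.atom_name): a.xyz for a in ref.receptor_atoms}
    out = []
    for i, cx in enumerate(complexes):
        if i == reference:
            out.append(cx)
            continue
        pairs = [(a, ref_map[(a.residue, a.atom_name)]) for a in cx.receptor_atoms
                 if (a.residue, a.atom_name) in ref_map]
        if len(pairs) < 3:
            logger.warning("superpose_complexes: too few shared atoms for %s; left unmoved", cx.id)
            out.append(cx)
            continue
        mobile = np.array([a.xyz for a, _ in pairs])
        target = np.array([r for _, r in pairs])
        R, t, _ = superpose(mobile, target)

        def mv(xyz: np.ndarray) -> tuple[float, float, float]:
            return tuple(R @ np.asarray(xyz) + t)

        out.append(Complex3D(
            receptor_atoms=[ReceptorAtom(a.chain, a.res_number, a.res_name, a.atom_name,
                                         a.element, mv(a.xyz)) for a in cx.receptor_atoms],
            ligand_atoms=[LigandAtom(a.index, a.element, mv(a.xyz), a.charge, a.n_hydrogens)
                          for a in cx.ligand_atoms],
            metadata=dict(cx.metadata),
        ))
    return out


def generate_queries(
    plif: PlifMatrix,
    complexes: Sequence[Complex3D],
    coverage_band: tuple[float, float] = (0.25, 0.75),
    max_radius: float = 3.0,
    excluded_volumes: bool = True,
    n_queries: int = 3,
    radius_floor: float = 0.5,
    seed: int = 0,
) -> list[PharmacophoreQuery]:
    """Turn contact frequencies into pharmacophore queries.

    A feature is emitted for every contact column whose frequency lies in
    the coverage band *or above it* -- near-universal contacts (the
    anchoring residues seen in nearly all complexes) are always kept.  The
    feature sits at the mean position of the ligand atoms that realized
    the contact, typed by the ligand-side role, with radius
    max(spread, ``radius_floor``) capped at ``max_radius``.  Receptor
    heavy atoms lining the site become excluded volumes.  Up to
    ``n_queries`` queries are produced by k-means clustering of the
    feature centroids.
    """
    low, high = coverage_band
    if low >= high:
        raise ValueError("coverage band low bound must be < high bound")
    if plif.bits.empty:
        raise ValueError("empty interaction matrix")

    freq = plif.frequencies
    feats: list[Feature] = []
    for col in plif.bits.columns:
        if freq[col] < low:
            continue
        coords, types = [], []
        for cx_id, contacts in plif.contacts.items():
            for c in contacts:
                if PlifMatrix.column_key(c.residue, c.kind) == col:
                    coords.append(c.ligand_coord)
                    types.append(c.ligand_feature_type)
        if not coords:
            continue
        coords = np.asarray(coords, dtype=float)
        centroid = coords.mean(axis=0)
        spread = float(np.linalg.norm(coords - centroid, axis=1).max()) if len(coords) > 1 else 0.0
        radius = min(max(spread, radius_floor), max_radius)
        ftype = max(set(types), key=types.count)
        feats.append(Feature(ftype, tuple(centroid), radius))

    if not feats:
        raise ValueError("no contact column reaches the coverage band")

    volumes: list[ExcludedVolume] = []
    if excluded_volumes and complexes:
        lig_coords = np.array([a.xyz for cx in complexes for a in cx.ligand_atoms])
        centroids = np.array([f.xyz for f in feats])
        seen = set()
        for atom in complexes[0].receptor_atoms:
            if atom.element == "H":
                continue
            d_lig = np.linalg.norm(lig_coords - atom.xyz, axis=1).min()
            d_feat = np.linalg.norm(centroids - atom.xyz, axis=1).min()
            # line the site, but stand clear of the features themselves
            if d_lig <= 5.0 and d_feat >= 2.0 and atom.coord not in seen:
                seen.add(atom.coord)
                volumes.append(ExcludedVolume(atom.coord, 1.0))

    k = max(1, min(n_queries, len(feats)))
    if k == 1:
        groups = [feats]
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assign = km.fit_predict(np.array([f.xyz for f in feats]))
        groups = [[f for f, g in zip(feats, assign) if g == gi] for gi in range(k)]
        groups = [g for g in groups if g]

    return [
        PharmacophoreQuery(features=g, excluded_volumes=list(volumes),
                           coverage_band=coverage_band, name=f"query{i + 1}")
        for i, g in enumerate(groups)
    ]


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def complex_from_pdb(path: str | Path, ligand_resname: str, metadata: dict | None = None) -> Complex3D:
    """Read a complex from a PDB file: receptor = ATOM records, ligand =
    HETATM records with the given residue code (waters never included)."""
    import biotite.structure.io.pdb as pdb

    pdbfile = pdb.PDBFile.read(str(path))
    arr = pdbfile.get_structure(model=1, extra_fields=["charge"])
    receptor, ligand = [], []
    lig_idx = 0
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).capitalize()
        coord = tuple(float(x) for x in arr.coord[i])
        if not arr.hetero[i]:
            receptor.append(ReceptorAtom(
                chain=str(arr.chain_id[i]), res_number=int(arr.res_id[i]),
                res_name=str(arr.res_name[i]), atom_name=str(arr.atom_name[i]),
                element=elem, coord=coord,
            ))
        elif str(arr.res_name[i]) == ligand_resname:
            ligand.append(LigandAtom(index=lig_idx, element=elem, coord=coord,
                                     charge=int(arr.charge[i])))
            lig_idx += 1
    meta = {"id": Path(path).stem}
    meta.update(metadata or {})
    return Complex3D(receptor_atoms=receptor, ligand_atoms=ligand, metadata=meta)


def complex_to_pdb(cx: Complex3D, path: str | Path, ligand_resname: str = "LIG") -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(cx.receptor_atoms) + len(cx.ligand_atoms)
    arr = struc.AtomArray(n)
    arr.add_annotation("charge", dtype=int)
    for i, a in enumerate(cx.receptor_atoms):
        arr.chain_id[i] = a.chain
        arr.res_id[i] = a.res_number
        arr.res_name[i] = a.res_name
        arr.atom_name[i] = a.atom_name
        arr.element[i] = a.element.upper()
        arr.hetero[i] = False
        arr.coord[i] = a.coord
    off = len(cx.receptor_atoms)
    for j, a in enumerate(cx.ligand_atoms):
        i = off + j
        arr.chain_id[i] = "X"
        arr.res_id[i] = 900
        arr.res_name[i] = ligand_resname
        arr.atom_name[i] = f"{a.element.upper()}{j + 1}"
        arr.element[i] = a.element.upper()
        arr.hetero[i] = True
        arr.charge[i] = a.charge
        arr.coord[i] = a.coord
    out = pdb.PDBFile()
    out.set_structure(arr)
    out.write(str(path))
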