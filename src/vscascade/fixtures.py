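"""Synthetic test-input generators.

Every stage of the cascade is exercisable without downloads: planted-signal
descriptor tables for the GA-SVM wrapper, scaffold-decorated toy chemical
libraries for decoy construction and Lipinski filtering, toy
ligand-receptor complexes with geometrically planted contacts for the PLIF
stage, and rank-noisy score tables for the NDCG comparison.  All generators
are pure functions of their arguments and the seed.
"""

from __future__ import annotations

import random
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset import MoleculeRecord
from .descriptors import DescriptorTable
from .plif import Complex3D, ContactRules, LigandAtom, ReceptorAtom
from .scoring import ScoreTable, pic50

# quinazolin-4(3H)-one core: decorating SMILES prefixes concatenate validly
DEFAULT_SCAFFOLD = "C1=NC2=CC=CC=C2C(=O)N1"

_TAILS = ["C", "CC", "CCC", "CCCC", "CCO", "CCN", "COC", "CN", "OC", "OCC",
          "CCCO", "CCCN", "CCOC", "NC", "NCC", "OCCC"]
_RINGS = ["C1CCCCC1", "C1CCOC1", "C1CCNC1", "C1CCCC1", "C1COCCO1",
          "C1CCNCC1", "C1CCSC1", "C1CCOCC1", "C1CCNC1=O", "C1CCC(=O)NC1",
          "C1CCC(=O)OC1", "C1CNC(=O)N1", "C1COC(=O)N1"]
_POLAR_TAILS = ["CC(=O)N", "CC(=O)O", "CC(=O)", "NC(=O)C", "OC(=O)C",
                "CNC(=O)C", "COC(=O)C", "NC(=O)"]


def gen_feature_table(
    n_pos: int,
    n_neg: int,
    n_features: int = 20,
    n_informative: int = 3,
    separation: float = 3.0,
    seed: int = 0,
) -> tuple[DescriptorTable, np.ndarray]:
    """Normalized descriptor table with a planted class signal.

    The first ``n_informative`` columns get a standardized class-mean
    difference of ``separation``; the rest are pure noise.  The informative
    column names are recorded in the table metadata.  Returns the table
    (state ``normalized``, scaling stored) and 0/1 labels.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    X = rng.normal(size=(n, n_features))
    X[y == 1, :n_informative] += separation
    cols = [f"desc{i:02d}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols, index=[f"m{i:04d}" for i in range(n)])
    scaling = {}
    for c in cols:
        lo, hi = float(df[c].min()), float(df[c].max())
        scaling[c] = (lo, hi)
        df[c] = (df[c] - lo) / (hi - lo)
    table = DescriptorTable(
        data=df, state="normalized", scaling=scaling,
        metadata={"informative": cols[:n_informative], "separation": separation, "seed": seed},
    )
    return table, y


def gen_chem_library(
    n_actives: int,
    n_inactives: int,
    scaffold: str = DEFAULT_SCAFFOLD,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """Toy chemical library: actives share a common scaffold with small
    decorations (mutually similar fingerprints), inactives are assembled
    from a diverse aliphatic fragment grammar (dissimilar to the actives).
    IC50s are log-uniform: actives in 0.01-10 uM, inactives in 100-10000 uM.
    """
    if Chem.MolFromSmiles(scaffold) is None:
        raise ValueError(f"unparsable scaffold {scaffold!r}")
    rng = random.Random(seed)
    records = []
    for i in range(n_actives):
        tail = rng.choice(_TAILS)
        if rng.random() < 0.5:
            tail = rng.choice(_TAILS) + tail
        smi = tail + scaffold
        mol = Chem.MolFromSmiles(smi)
        ic50 = 10 ** rng.uniform(-2, 1)  # 0.01 .. 10 uM
        records.append(MoleculeRecord(id=f"act{i:04d}", structure=mol, ic50=ic50))
    for i in range(n_inactives):
        smi = rng.choice(_TAILS + _POLAR_TAILS) + rng.choice(_RINGS)
        if rng.random() < 0.5:
            smi = rng.choice(_TAILS + _POLAR_TAILS) + smi
        mol = Chem.MolFromSmiles(smi)
        ic50 = 10 ** rng.uniform(2, 4)  # 100 .. 10000 uM
        records.append(MoleculeRecord(id=f"ina{i:04d}", structure=mol, ic50=ic50))
    return records


def _residue_atoms(chain: str, number: int, name: str, base: np.ndarray, kind: str) -> list[ReceptorAtom]:
    """A minimal residue whose interaction atom satisfies ``kind``'s rule
    when the ligand partner is placed down the +x axis."""
    ca = ReceptorAtom(chain, number, name, "CA", "C", tuple(base))
    x = np.array([2.0, 0.0, 0.0])
    if kind == "hbond_donor":
        inter = ReceptorAtom(chain, number, name, "N", "N", tuple(base + x))
    elif kind == "hbond_acceptor":
        inter = ReceptorAtom(chain, number, name, "O", "O", tuple(base + x))
    elif kind == "ionic":
        # a lysine-like cationic head; use ASP naming for the anionic case
        if name == "ASP":
            inter = ReceptorAtom(chain, number, name, "OD1", "O", tuple(base + x))
        else:
            inter = ReceptorAtom(chain, number, name, "NZ", "N", tuple(base + x))
    elif kind == "hydrophobic":
        inter = ReceptorAtom(chain, number, name, "CB", "C", tuple(base + x))
    else:
        raise ValueError(f"unknown contact kind {kind!r}")
    return [ca, inter]


def _ligand_partner(kind: str, inter_xyz: np.ndarray, res_name: str, index: int,
                    rules: ContactRules) -> LigandAtom:
    x = np.array([1.0, 0.0, 0.0])
    if kind == "hbond_donor":  # receptor donates -> neutral ligand acceptor O
        return LigandAtom(index, "O", tuple(inter_xyz + rules.hbond_dist_ideal * x), 0, 0)
    if kind == "hbond_acceptor":  # receptor accepts -> protonated ligand N
        return LigandAtom(index, "N", tuple(inter_xyz + rules.hbond_dist_ideal * x), 0, 2)
    if kind == "ionic":
        charge = 1 if res_name == "ASP" else -1
        elem = "N" if charge > 0 else "O"
        return LigandAtom(index, elem, tuple(inter_xyz + rules.ionic_dist_ideal * x), charge, 0)
    if kind == "hydrophobic":
        return LigandAtom(index, "C", tuple(inter_xyz + rules.hydrophobic_dist_ideal * x), 0, 3)
    raise ValueError(f"unknown contact kind {kind!r}")


def gen_complex_set(
    n_complexes: int,
    planted_contacts: Sequence[tuple[tuple[str, int, str], str, float]],
    seed: int = 0,
    rules: ContactRules | None = None,
) -> list[Complex3D]:
    """Toy aligned complexes with contacts planted at given frequencies.

    ``planted_contacts`` lists ((chain, number, resname), kind, frequency);
    each contact's geometry satisfies its detection rule exactly and is
    realized in ``round(frequency * n_complexes)`` complexes (a seeded
    sample).  Residues sit 15 Angstrom apart so planted contacts never
    interfere; every ligand also carries one inert far-away carbon so no
    ligand is empty.
    """
    rules = rules or ContactRules()
    rng = random.Random(seed)
    for (_, _, _), kind, freq in planted_contacts:
        if not (0 <= freq <= 1):
            raise ValueError("frequencies must lie in [0, 1]")

    residues = []
    for i, (res, kind, freq) in enumerate(planted_contacts):
        base = np.array([0.0, 15.0 * i, 0.0])
        residues.append((res, kind, freq, base))
    receptor = [a for res, kind, _, base in residues
                for a in _residue_atoms(res[0], res[1], res[2], base, kind)]

    realized: list[set[int]] = []
    for _, _, freq, _ in residues:
        k = round(freq * n_complexes)
        realized.append(set(rng.sample(range(n_complexes), k)))

    complexes = []
    for ci in range(n_complexes):
        ligand = []
        for (res, kind, _, base), members in zip(residues, realized):
            if ci in members:
                inter_xyz = base + np.array([2.0, 0.0, 0.0])
                ligand.append(_ligand_partner(kind, inter_xyz, res[2], len(ligand), rules))
        ligand.append(LigandAtom(len(ligand), "C", (0.0, -50.0, 0.0), 0, 3))  # inert anchor
        complexes.append(Complex3D(
            receptor_atoms=list(receptor), ligand_atoms=ligand,
            metadata={"id": f"cx{ci:03d}", "seed": seed},
        ))
    return complexes


def gen_score_table(
    ic50s: Mapping[str, float],
    n_columns: int = 4,
    rank_noise: Sequence[float] = (0.0, 1.0, 2.0, 4.0),
    seed: int = 0,
) -> ScoreTable:
    """Score columns = pIC50 plus per-column Gaussian rank noise.

    A noise-0 column ranks molecules exactly by potency (NDCG 1); noisier
    columns degrade in expectation, emulating scoring functions of varying
    fidelity.  All columns are flagged higher-is-better.
    """
    if len(rank_noise) != n_columns:
        raise ValueError("rank_noise must provide one level per column")
    if any(s < 0 for s in rank_noise):
        raise ValueError("rank_noise must be >= 0")
    rng = np.random.default_rng(seed)
    ids = list(ic50s)
    rel = np.array([pic50(ic50s[i]) for i in ids])
    data = {}
    for j, sigma in enumerate(rank_noise):
        data[f"fn{j + 1}"] = rel + sigma * rng.normal(size=len(ids))
    df = pd.DataFrame(data, index=ids)
    return ScoreTable(data=df, direction={c: "higher_is_better" for c in df.columns})
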