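# vscascade

Hierarchical multistage virtual screening for selective kinase inhibitor
discovery, built as a reusable Python library. The workflow it implements
was developed for finding PI3Kδ-selective inhibitors — the delta isoform of
phosphoinositide 3-kinase, an immune-signalling target where selectivity
over the α/β/γ isoforms decides the side-effect profile — but every stage
is generic ligand-based screening machinery:

1. **Dataset construction** — label compounds by IC50 cutoffs (active
   ≤ 10 μM, inactive ≥ 100 μM, gray zone discarded), and build
   property-matched decoy sets: candidates whose ECFP4 Tanimoto coefficient
   to *every* active is < 0.5 but whose five physical properties (MW, H-bond
   donors/acceptors, rotatable bonds, logP) fall within a window of at least
   one active.
2. **Descriptor pipeline** — compute molecular descriptors through a
   pluggable backend (default: RDKit's 2D set), drop null/constant columns,
   near-constant columns (coefficient of variation < 0.5%), and correlated
   columns (|r| > 0.95), then min-max normalize to [0, 1], keeping the
   scaling to project screening libraries into the training domain.
3. **GA-SVM** — genetic-algorithm wrapper selection of a descriptor subset
   whose fitness is the stratified k-fold cross-validated accuracy of an
   RBF-SVM, plus (C, γ) grid search and pooled confusion-count evaluation
   (SE/SP/Q).
4. **PLIF pharmacophore** — geometric protein–ligand contact detection over
   a set of superposed complexes, per-residue interaction-type bit matrix,
   and pharmacophore queries generated from contact *frequencies*: columns
   inside or above a 25–75% coverage band become typed feature spheres
   (radius ≤ 3 Å) with receptor-derived excluded volumes; ligand conformers
   are matched by exhaustive rigid alignment.
5. **Scoring/NDCG** — ingest externally produced docking score tables and
   pick the score column most consistent with measured potency by
   normalized discounted cumulative gain with relevance `rel_i = pIC50`:

   `DCG_p = rel_1 + Σ_{i=2..p} rel_i / log2(i)`, `NDCG_p = DCG_p / IDCG_p`

   then apply an inclusive threshold stage with calibratable cutoff.
6. **Cascade evaluation** — compose stages so each sees only the previous
   stage's survivors, with per-stage confusion accounting and the screening
   metrics `SE = 100·TP/(TP+FN)`, `SP = 100·TN/(TN+FP)`,
   `Q = 100·(TP+TN)/N`, yield (= SE), `hit rate = 100·TP/(TP+FP)` and
   `EF = (hit rate/100)/base_fraction`; stage ordering by exhaustive
   permutation search; Lipinski rule-of-five drug-likeness filter.

A `fixtures` module generates every kind of test input synthetically
(planted-signal descriptor tables, scaffold-decorated toy libraries, toy
complexes with geometrically planted contacts, rank-noisy score tables), so
the whole cascade runs without any external download.

## Worked example

Each capability has a narrative script under `examples/`. For instance the
interaction-fingerprint stage (`python examples/04_plif_pharmacophore.py`):

```
contact frequencies (fraction of complexes with the contact):
  A:828:VAL|hbond_donor          0.944
  A:826:GLU|hbond_acceptor       0.500
  A:752:MET|hydrophobic          0.111

query features: [('acceptor', 0.5), ('donor', 0.5)]
excluded volumes from receptor atoms: 5
self-match: matched=True, alignment RMSD=6.59e-16 A
```

Eighteen toy complexes carry a hydrogen-bond contact to residue Val828 in
17 of them, so its fingerprint column has frequency 17/18 = 94.4% — the
signature of a conserved hinge interaction. That anchor (above the 25–75%
coverage band) and the in-band Glu826 contact become feature spheres; the
11% hydrophobic contact falls below the band and is dropped. A ligand whose
feature points generated the query matches it back with zero RMSD.

The cascade composition (`python examples/06_cascade.py`) prints per-stage
survivor accounting:

```
  svm             300 ->   72 survivors  yield= 86.8%  hit rate= 63.9%  EF=3.62
  pharmacophore    72 ->   48 survivors  yield= 71.7%  hit rate= 79.2%  EF=4.48
  docking          48 ->   32 survivors  yield= 58.5%  hit rate= 96.9%  EF=5.48
```

Yield falls as stages stack (each filter loses some true actives) while hit
rate and enrichment rise — the core trade-off of multistage screening.

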