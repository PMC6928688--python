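# Methods

This note records the models, parameter choices and numerical conventions
behind `vscascade`, and what the synthetic fixtures do and do not show.

## Dataset construction

Activity labelling uses two inclusive cutoffs on IC50 in μM: ≤ 10 μM is
active, ≥ 100 μM inactive. Compounds strictly between the cutoffs are
excluded from labelled output altogether; the buffer zone keeps borderline
binders out of the negative class, which would otherwise inflate false
positives downstream. Records without an IC50 are retained unlabeled.
Duplicates are removed by canonical SMILES, first occurrence winning.

Decoy selection applies two predicates: (a) circular-fingerprint
(Morgan radius 2, 2048 bits — the de-facto ECFP4 convention; parameters are
written into the output metadata) Tanimoto < `tc_max` (default 0.5)
against *every* active, and (b) all five physical properties (MW, HBD,
HBA, rotatable bonds, logP) within a tolerance window of *at least one*
active. Window defaults (±40 Da, ±1, ±2, ±1, ±1.0 log units) follow the
published defaults of the DecoyFinder-style property-matching approach and
are all overridable. Each candidate counts against the first active (input
order) whose window it satisfies, capped at 36 decoys per active;
candidates are scanned in id order so the output is deterministic. The
Tanimoto of two empty fingerprints is defined as 0, since an empty
fingerprint signals a degenerate structure.

Splits are drawn without replacement from shuffled pools under a fixed
seed; a count of −1 means "all remaining". Requests exceeding a pool raise
a sizing error stating the shortfall.

## Descriptor pipeline

Descriptor computation is a pluggable backend contract (a named descriptor
list plus a per-molecule `compute`). The default backend is RDKit's 2D
descriptor set (~210 descriptors); the backend name and count are recorded
in the table metadata. A backend failure on one molecule leaves that row
missing rather than aborting the table.

The redundancy filter applies three rules in order:

1. columns with > 5% missing values, constant columns, or all-zero columns;
2. columns whose coefficient of variation (sd / |mean|) is below 0.005.
   "Relative standard deviation below 0.5%" admits several readings; the
   sd-relative-to-range reading is provably vacuous (for n points the
   minimum attainable sd/range is 1/√(2(n−1)), ≈ 0.0074 even at n ≈ 9000),
   so the coefficient-of-variation reading is used. The rule text is
   written into every `FilterReport` for auditability. Columns with mean
   ≈ 0 are kept: relative spread is ill-defined there and rule 1 already
   removed true constants;
3. pairs with |Pearson r| > 0.95: columns are scanned in input order and
   the *later* member of each offending pair is dropped — deterministic
   and order-stable.

Rows are never dropped for missingness; remaining gaps are imputed with
the column median before the correlation scan, keeping labelled sets
intact. Normalization is per-column min-max to [0, 1] with the (min, max)
pairs stored; screening libraries are projected through the stored scaling
with out-of-range values clipped to [0, 1], so the SVM never sees inputs
outside its training domain.

## GA-SVM

The wrapper encodes a descriptor subset as a bitstring chromosome.
Defaults: population 50, 100 generations, tournament selection (size 3),
one-point crossover at rate 0.8, per-bit mutation 1/length, elitism 1,
fitness = mean stratified k-fold (default 10) CV accuracy of an RBF-SVM on
the selected columns, ties broken toward fewer descriptors (a mild
parsimony pressure). All of this sits in `GaConfig`. The initial
population always contains the all-columns chromosome, so the winner can
never score below the full descriptor set on the shared fold assignment.
Fitness evaluations are cached per chromosome; everything is reproducible
from `GaConfig.seed`.

No class weighting is applied by default (matching the high-specificity
regime such campaigns report on imbalanced decoy-heavy training sets);
scikit-learn's `SVC` accepts weighting through the params if needed.

Grid search is exhaustive over C ∈ {2⁻²…2⁶} and γ ∈ {10⁻³…1} (log-spaced)
by default, ties broken toward smaller C then smaller γ — the least
complex model among equals. Cross-validation pools (not averages)
out-of-fold confusion counts, so TP+FN and TN+FP exactly partition the
classes and the counts are integers.

## PLIF pharmacophore

Contact detection is geometric, standing on its own terms (commercial
interaction-fingerprint scores are proprietary):

- hydrogen bond: donor/acceptor heavy atoms ≤ 3.5 Å apart and, when the
  donor's bonded neighbour is known, an antecedent–donor···acceptor angle
  ≥ 120°. Bare ligand atoms (no recorded bonds) pass the angle test by
  construction;
- ionic: opposite formal charges ≤ 4.0 Å apart; ligand atoms with nonzero
  formal charge are excluded from the hydrogen-bond rules so the two
  contact kinds stay disjoint;
- hydrophobic: carbon–carbon ≤ 4.5 Å.

Each contact carries a pseudo-energy = kind-specific depth × a linear
falloff from the ideal distance (2.8 / 3.0 / 3.8 Å) to the cutoff, so the
score decreases monotonically as geometry degrades. Contacts below 0.5
(the weak threshold) are suppressed; 1.5 marks the strong tier.

The fingerprint matrix holds one row per complex and one column per
(residue, interaction kind), columns sorted by frequency descending.
Superposition into a common frame is the caller's responsibility; a
Kabsch-based helper pairs receptor atoms by (chain, residue, atom name).

Query generation emits a feature for every column whose frequency is
inside the 25–75% coverage band **or above it** — near-universal anchor
contacts are always kept. The feature centroid is the mean position of the
ligand atoms that realized the contact, typed by the ligand-side role
(a residue that donates implies a ligand acceptor, and so on); radius =
max(spread, 0.5 Å) capped at 3 Å. Receptor heavy atoms within 5 Å of any
ligand atom, but ≥ 2 Å from every feature centroid, become excluded
volumes of radius 1 Å. Up to k (default 3) queries are produced by
k-means clustering of feature centroids, reflecting workflows that carry
a small family of queries rather than one.

Matching is exhaustive rigid search: every injective assignment of
required query features to same-typed ligand features is scored by Kabsch
superposition; a placement succeeds when every assigned feature lands
within its sphere and no ligand atom penetrates an excluded volume. The
default policy requires all features ("AND"); an n−1 policy is available.
Conformers (default 10 per molecule) come from seeded ETKDG embedding;
ligand feature typing uses small auditable SMARTS rules (H-bearing N/O
donors, lone-pair N/O acceptors, aromatic ring centroids, aliphatic carbon
clusters, charged/protonatable groups), not a full perception model.

## Scoring and NDCG

Scores arrive as external tables with a mandatory per-column direction
flag. Relevance is pIC50 = −log10(IC50·10⁻⁶) from μM. The gain is

    DCG_p = rel_1 + Σ_{i=2..p} rel_i / log2(i),   NDCG_p = DCG_p / IDCG_p,

with the ideal ordering sorted by relevance descending, ties broken by id
for a deterministic denominator; tied scores keep input order (the
discount is order-sensitive, so this is stated rather than left to chance).
One structural property worth knowing: ranks 1 and 2 carry the same
discount weight (rel₂ is divided by log2(2) = 1), so exchanging the top
two items leaves NDCG at exactly 1 — "NDCG = 1" means potency-sorted up to
ties and up to that top-2 exchange. NDCG is invariant under any strictly
monotone transform of the scores.

Threshold stages are boundary-inclusive in the column's direction, which
makes survivors monotone in the cutoff. Because the upstream pass mark of
an external docking run is rarely published, `calibrate_cutoff` scans
unique score values for max-EF, max-Youden or a target-yield objective
(ties resolve to the more permissive cutoff).

## Cascade evaluation

Stages are pass/fail predicates with a relative cost hint; an exception
inside a predicate counts that molecule as screen-negative, so malformed
inputs degrade a screen instead of crashing it. Each stage sees only the
previous stage's survivors; with truth supplied, per-stage confusion is
computed over the original library so the last stage's counts are the
cascade's overall counts, and survivor nesting is asserted on every run.
Ordering evaluates all permutations (≤ 6 for three stages) on a labelled
validation library under max-EF or cost-then-EF, with deterministic
name-based tie-breaks.

Metrics follow their definitions exactly: SE = 100·TP/(TP+FN),
SP = 100·TN/(TN+FP), Q = 100·(TP+TN)/total, yield ≡ SE,
hit rate = 100·TP/(TP+FP), EF = (hit rate/100)/base_fraction with the
base fraction always an explicit argument. This explicitness is
deliberate: published composite screening runs often print enrichment
numbers whose denominators cannot be recovered from the printed counts
(e.g. a run retrieving 112 actives with 50 surviving decoys from a
175/132,914 validation set has, by definition, hit rate 112/162 = 69.1%
and EF ≈ 526 — irreconcilable with the printed 75.1% and 301.66). The
package therefore never infers a base rate and reports only what its
formulas produce. Display rounding is one decimal for percentages and two
for EF; tests compare unrounded values.

The Lipinski filter checks MW ≤ 500 Da, logP ≤ 5, donors ≤ 5,
acceptors ≤ 10 and tolerates one violation by default (common practice);
`max_violations=0` gives the strict variant.

## Synthetic fixtures

The generators emulate the *structure* of a screening campaign, not its
chemistry or physics:

- feature tables plant a standardized class-mean separation (default 3 SD)
  in a known subset of columns — enough signal that stage behaviour is
  unambiguous at n ≈ 100–1000 and selection tests are not flaky;
- toy libraries decorate a quinazolinone-like scaffold for actives (high
  mutual Tanimoto) and assemble inactives from an aliphatic/polar fragment
  grammar (low Tanimoto to actives), with log-uniform IC50s on the active
  (≤ 10 μM) and inactive (≥ 100 μM) sides;
- toy complexes realize each planted contact with geometry that satisfies
  its detection rule exactly, residues spaced 15 Å apart so contacts never
  interfere, each realized in round(frequency × n) complexes;
- score tables add per-column Gaussian noise to pIC50, so the least noisy
  column has the highest expected NDCG.

Passing tests on these fixtures demonstrates correct bookkeeping,
geometry, optimization and metric arithmetic — they say nothing about
performance on real chemical matter, where descriptor redundancy,
activity cliffs, conformational strain and binding-site plasticity are the
hard parts. The acceptance script runs the GA recovery at 400 samples ×
20 descriptors over ten seeds and the end-to-end cascade at 440 molecules;
these sizes were chosen as the smallest at which the planted effects are
clearly resolved.

## Known limitations

- Contact rules are heavy-atom geometric heuristics; no explicit hydrogen
  placement, π-stacking, halogen bonds or water-mediated contacts.
- Pharmacophore matching is rigid per conformer; torsional flexibility is
  only represented through the conformer ensemble.
- The descriptor backend contract cannot reproduce proprietary descriptor
  sets; models trained on different backends are not comparable.
- Docking scores are ingested, never computed; the threshold stage is only
  as good as the external score table.
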