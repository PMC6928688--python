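"""Build a labelled actives/decoys dataset with reproducible splits.

Generates a toy library, labels it by IC50 cutoffs (<= 10 uM active,
>= 100 uM inactive, the gray zone dropped), selects property-matched
topologically dissimilar decoys, and draws disjoint splits.
"""

from vscascade import PropertyWindow, find_decoys, fixtures, label_by_activity, make_splits

lib = fixtures.gen_chem_library(n_actives=10, n_inactives=300, seed=7)
labelled = label_by_activity(lib, pos_cutoff=10.0, neg_cutoff=100.0)
actives = [r for r in labelled if r.label == "active"]
candidates = [r for r in labelled if r.label == "inactive"]

decoys = find_decoys(actives, candidates, tc_max=0.5, window=PropertyWindow())
print(f"{len(actives)} actives, {len(candidates)} candidates -> {len(decoys)} decoys")
print("a decoy is similar in its five physical properties to some active,")
print("but its fingerprint Tanimoto to every active stays below 0.5")

split = make_splits(
    actives, decoys,
    spec={"training": {"actives": 6, "decoys": -1}, "test": {"actives": 4}},
    seed=7,
)
print(f"training: {len(split.training)} molecules, test: {len(split.test)} molecules")
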