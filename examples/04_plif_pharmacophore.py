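"""Interaction fingerprints and frequency-derived pharmacophore queries.

18 toy complexes share an anchor hydrogen bond in 17 of them (94.4%, the
structure of a conserved hinge contact); contact frequencies inside or
above the 25-75% coverage band become typed feature spheres, and a
ligand whose features generated the query matches it back.
"""

from vscascade import build_plif, fixtures, generate_queries, match_ligand
from vscascade.pharmacophore import LigandFeatureSet

planted = [
    (("A", 828, "VAL"), "hbond_donor", 17 / 18),   # anchor: kept although above band
    (("A", 826, "GLU"), "hbond_acceptor", 0.5),    # in band
    (("A", 752, "MET"), "hydrophobic", 0.1),       # below band: dropped
]
complexes = fixtures.gen_complex_set(18, planted, seed=42)
plif = build_plif(complexes)
print("contact frequencies (fraction of complexes with the contact):")
for col, freq in plif.frequencies.items():
    print(f"  {col:30s} {freq:.3f}")

queries = generate_queries(plif, complexes, coverage_band=(0.25, 0.75),
                           max_radius=3.0, n_queries=1)
q = queries[0]
print(f"\nquery features: {[(f.type, round(f.radius, 2)) for f in q.features]}")
print(f"excluded volumes from receptor atoms: {len(q.excluded_volumes)}")

self_lig = LigandFeatureSet("self", 0, list(q.features))
ok, rmsd = match_ligand(q, self_lig)
print(f"self-match: matched={ok}, alignment RMSD={rmsd:.2e} A")
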