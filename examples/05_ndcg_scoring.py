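"""Choose the scoring function most consistent with measured potency.

Four synthetic score columns carry increasing rank noise around pIC50;
NDCG (relevance = pIC50) identifies the most potency-consistent column,
which then drives a calibrated threshold stage.
"""

from vscascade import calibrate_cutoff, fixtures, ndcg, pic50, select_scoring_function, threshold_stage

ic50s = {f"mol{i:02d}": 10 ** (-i / 5) for i in range(20)}  # 1 uM down to ~0.0001 uM
table = fixtures.gen_score_table(ic50s, n_columns=4, rank_noise=(0.0, 1.0, 2.0, 4.0), seed=1)

best, per_column = select_scoring_function(table, ic50s)
print("NDCG of each scoring function against pIC50 (1 = potency-perfect ranking):")
for col, val in per_column.items():
    marker = "  <- selected" if col == best else ""
    print(f"  {col}: {val:.4f}{marker}")

labels = {k: v <= 0.05 for k, v in ic50s.items()}  # potent half as "actives"
cutoff = calibrate_cutoff(table, best, labels, objective="max_EF")
survivors = threshold_stage(table, best, cutoff)
print(f"\ncalibrated cutoff {cutoff:.3f} keeps {len(survivors)} of {len(ic50s)} molecules")
print(f"actives among survivors: {sum(labels[i] for i in survivors)}")
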