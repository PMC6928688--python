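"""Descriptor preprocessing: compute, filter redundancy, normalize.

The three filter rules drop null/constant columns, columns with
near-zero relative spread, and the later member of every highly
correlated pair (|r| > 0.95); survivors are min-max scaled to [0, 1]
and the scaling is kept for projecting new screening libraries.
"""

from vscascade import apply_scaling, compute_descriptors, filter_descriptors, fixtures, normalize

lib = fixtures.gen_chem_library(10, 40, seed=3)
raw = compute_descriptors(lib)  # default backend: RDKit 2D descriptor set
print(f"raw table: {raw.data.shape[0]} molecules x {raw.data.shape[1]} descriptors")

filtered, report = filter_descriptors(raw, null_frac_max=0.05, stdev_min=0.005, corr_max=0.95)
print(f"dropped {len(report.dropped_null)} null/constant, "
      f"{len(report.dropped_lowvar)} low-variance, "
      f"{len(report.dropped_correlated)} correlated -> {len(report.retained)} retained")

norm = normalize(filtered)
print(f"normalized: every column spans [{norm.data.min().min():.0f}, {norm.data.max().max():.0f}]")

# screening a new library reuses the training scaling (values clipped to [0,1])
newlib = fixtures.gen_chem_library(5, 5, seed=4)
projected = apply_scaling(compute_descriptors(newlib), norm.scaling)
print(f"projected new library: {projected.data.shape}, in training domain")
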