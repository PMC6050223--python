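"""Generate a synthetic RGC experiment and write it as a 10x-style fixture.

The generator plants everything the downstream analyses look for: nested
subtype structure, unique markers, TF combinations, eye imbalance, a
low-coverage sub-peak and a contaminant cell fraction.
"""

import rgcsub as rs

cfg = rs.desk_config(seed=1, n_cells=1200)
counts, truth = rs.generate(cfg)
paths = rs.write_fixture(counts, truth, "scratch_fixture")

print(f"cells x genes: {counts.shape}")
print(f"clusters: {cfg.n_clusters}, ISPs: {cfg.n_isps}, superclusters: {cfg.n_superclusters}")
print(f"planted markers per cluster: {cfg.markers_per_cluster} at linear fold {cfg.marker_fold}")
print(f"planted TF combinations: {dict(truth.combo_map)}")
print(f"low-coverage cells: {len(truth.low_quality_cells)}, contaminants: {len(truth.contaminant_cells)}")
for name, p in paths.items():
    print(f"wrote {name}: {p}")
# The MTX triplet round-trips through rgcsub.read_counts; truth.json carries
# the planted labels for recovery scoring.
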