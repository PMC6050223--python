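"""End-to-end pipeline: simulate -> QC -> NE -> cluster -> every analysis.

Writes all artifacts (embedding TSV, marker/census/laterality CSVs, newick
tree, ISP tables, TF-combination table, JSON summary, log) into one
directory.  Reruns with the same seed are byte-identical.

Equivalent shell command:  rgcsub all --seed 5 --out pipeline_out
"""

import json

import rgcsub as rs

cfg = rs.PipelineConfig(seed=5, min_genes=250, n_super=2, n_isp=2, max_k=2, anova_max_combos=2)
cfg.sim.update(n_cells=900, n_genes=900, n_clusters=4, n_isps=2,
               n_superclusters=2, markers_per_cluster=3,
               separation_pair_genes=120, tf_panel_size=10,
               planted_combos=((1, ("Tf01", "Tf02")),))

paths = rs.run_pipeline(cfg, "pipeline_out")
summary = json.loads(paths["summary"].read_text())
print(f"clusters found: {summary['n_clusters']}")
print(f"contaminants excluded: {summary['excluded_contaminant_pct']}% of round-1 cells")
print(f"chi-squared df: {summary['chi_square']['df']}")
print(f"bulk concordance r: {summary['bulk_concordance_r']}")
print(f"marker records: {summary['n_marker_records']}, "
      f"TF combinations: {summary['n_tf_combinations']}")
for name, p in sorted(paths.items()):
    print(f"  {name}: {p}")
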