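"""Subtype diversification: dendrogram, supercluster/ISP cuts, ISP genes.

The tree is Ward linkage over Chebyshev (maximum) distances between cluster
mean-NE profiles; horizontal cuts at two depths give nested superclusters
and intermediate subpopulations (ISPs).  ISP-enriched genes must pass the
unique-enrichment rule on merged profiles AND in every member cluster.
"""

import numpy as np

import rgcsub as rs
from rgcsub.io import GenePanel

counts, truth = rs.generate(rs.desk_config(seed=4))
filtered, _ = rs.filter_low_coverage(counts, rs.simulate.DESK_QC_MIN_GENES)
ne = rs.normalize_ne(filtered)
idx = {b: i for i, b in enumerate(truth.barcodes)}
keep = [b for b in ne.obs_names if truth.cell_cluster[idx[b]] > 0]
labels = np.array([truth.cell_cluster[idx[b]] for b in keep])
cr = rs.ClusterResult(labels=labels,
                      embedding=rs.Embedding(np.zeros((len(keep), 3)), keep, 0))
ne_t = ne[keep].copy()
prof = rs.profile(ne_t, cr)

tree = rs.build_tree(prof)  # chebyshev + ward
print("newick:", rs.to_newick(tree))

isps = rs.cut_isps(tree, prof, n_super=2, n_isp=4)
for isp in sorted(isps.prevalence.index):
    members = isps.members(isp)
    print(f"ISP {isp} (supercluster {isps.isp_to_supercluster[isp]}): "
          f"subtypes {members}, {100 * isps.prevalence[isp]:.1f}% of cells")
print("planted nesting:", truth.cluster_to_isp)

tfs = GenePanel("tf", tuple(counts.uns["panels"]["tf"]), "tf")
enriched = rs.isp_enriched(ne_t, cr, prof, isps, tfs=tfs)
for isp, df in enriched.items():
    names = ", ".join(df.gene.head(6)) or "-"
    print(f"ISP {isp} enriched genes (verified in every member cluster): {names}")
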