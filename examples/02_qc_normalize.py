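"""QC-filter a count matrix and convert it to NE units.

NE (normalized expression) is counts scaled by the median library size and
log2-transformed with a +1 pseudocount; every downstream threshold (0.05 NE
marker floor, 0.5 NE TF floor, 1.8-fold enrichment) is stated in NE.
"""

import numpy as np

import rgcsub as rs

counts, truth = rs.generate(rs.desk_config(seed=1, n_cells=1500))

detected = rs.genes_detected(counts)
print(f"genes detected per cell: median {int(np.median(detected))}, "
      f"low-coverage sub-peak below ~{rs.simulate.DESK_QC_MIN_GENES}")

filtered, removed = rs.filter_low_coverage(counts, rs.simulate.DESK_QC_MIN_GENES)
print(f"QC removed {len(removed)} of {counts.n_obs} cells "
      f"({100 * len(removed) / counts.n_obs:.1f}%; planted low-quality fraction is 6%)")

ne = rs.normalize_ne(filtered)
print(f"median of per-cell totals M = {ne.uns['ne']['M']:.0f}")

# worked example: totals 100 and 200 -> M = 150; a count of 10 in the
# 100-total cell maps to log2(10 * 150/100 + 1) = log2(16) = 4.0
import anndata as ad
import pandas as pd
row1 = np.zeros(20); row1[0] = 10; row1[1:10] = 10
row2 = np.zeros(20); row2[10:] = 20
toy = ad.AnnData(X=np.vstack([row1, row2]),
                 obs=pd.DataFrame(index=["a", "b"]),
                 var=pd.DataFrame(index=[f"g{j}" for j in range(20)]))
print(f"worked example NE = {np.asarray(rs.normalize_ne(toy).X)[0, 0]:.1f} (expected 4.0)")

genes = rs.select_overdispersed(ne, n=500)
print(f"top over-dispersed genes (variance/mean NE), first 5: {genes[:5]}")
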