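# rgcsub

Single-cell RNA-seq subtype discovery for retinal ganglion cells (RGCs):
a tested, reusable implementation of the analysis chain that classifies a
purified neuronal cell-type population into transcriptomic subtypes and
characterizes what distinguishes them — unique marker genes, left/right-eye
laterality, a diversification hierarchy, and combinatorial
transcription-factor (TF) signatures.

RGCs are the retina's output neurons. Droplet scRNA-seq of immunopanned
RGCs yields a UMI count matrix over thousands of cells from left and right
eyes; the pipeline implemented here takes such a matrix to a full subtype
atlas. Because the interesting guarantees are statistical (does the method
find what is truly there?), the package ships a synthetic-data generator
with planted ground truth and tests every stage end-to-end against it.

## The analysis

1. **QC** — cells below a genes-detected cutoff (the low-coverage sub-peak)
   are excluded.
2. **Normalization** — NE (normalized expression):
   `NE_gc = log2(x_gc * M / T_c + 1)`, with `T_c` the cell's total UMIs and
   `M` the median of totals. Every downstream threshold is in NE units.
3. **Two-round clustering** — the 1000 most over-dispersed genes
   (variance/mean of NE, sex-specific genes excluded) are embedded with 3-D
   Barnes-Hut t-SNE (PCA to 10 components first; perplexity 30, 1000
   iterations) and clustered with DBSCAN (eps = 5.0, minpts = 15; noise →
   cluster 0). Clusters whose non-RGC (contaminant) panel expression beats
   the RGC panel are removed, genes re-selected, and the survivors
   re-clustered.
4. **Unique markers** — genes expressed > 1.8-fold above *every* other
   cluster and > 0.05 NE; the top candidates per cluster are graded by
   Welch t and Mann–Whitney U tests against every other cluster.
5. **Laterality** — eye × cluster contingency: Pearson χ² (df = K−1),
   per-cluster two-proportion z-tests with Bonferroni correction, mirror
   correlations of eye-specific cluster profiles.
6. **Hierarchy** — Ward linkage over Chebyshev (maximum) distances between
   cluster mean-NE profiles; horizontal cuts give superclusters and
   intermediate subpopulations (ISPs); ISP-enriched genes are verified in
   every member cluster.
7. **TF combinations** — TFs binarized per cluster (> 0.5 NE and > 2× their
   mean NE across clusters); all subsets up to 5 TFs ANDed; patterns
   lighting exactly one cluster, with no unique proper subset, are that
   subtype's signature. A relaxed 1.5× rerun cross-references the list, and
   a mixed-design ANOVA (TF within-cell × cluster between-cells) supplies
   interaction p-values.

## Worked example

```sh
python examples/03_cluster_subtypes.py
```

```
final clusters: K = 8 (planted: 8)
excluded as contaminant clusters: 45 cells = 3.2% of round-1 cells
unassigned (cluster 0): 0 cells
adjusted Rand index vs planted subtypes: 1.000 (1.0 = perfect recovery)
```

The generator planted 8 subtypes (nested 2-per-ISP under 2 superclusters)
plus 4% contaminant cells in a 1500-cell experiment; the two-round pipeline
finds exactly the planted partition and removes the contaminant cluster.
`examples/` holds one short script per capability (simulation and fixtures,
QC/normalization, clustering, markers, laterality, hierarchy/ISPs, TF
combinations, end-to-end pipeline); each prints the numbers it computes and
what they mean. A thin CLI covers the shell use-cases:

```sh
rgcsub simulate --seed 1 --n-cells 3000 --out fixture/
rgcsub all --seed 1 --out pipeline_out/
```

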