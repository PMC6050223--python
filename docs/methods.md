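# Methods

## Normalization (NE units)

Counts are scaled per cell by `M / T_c` — `T_c` the cell's total UMIs, `M`
the median of totals across cells (an even number of cells takes the mean
of the two middle values) — then transformed `log2(x + 1)`. Zero counts map
exactly to NE 0 and NE is strictly increasing in the count within a cell.
A zero-total cell cannot be scaled and is reported as an error by barcode.
Normalization follows QC filtering, so `M` is computed over retained cells
only. The implementation is cross-checked in the test-suite against
scanpy's median library-size normalization with a base-2 log1p.

## QC cutoff

Cells are dropped when they detect fewer than `min_genes` genes
(default 3000, the value appropriate to a full mouse transcriptome). On the
desk-scale simulation (2000 genes total) the same rule is applied at
`DESK_QC_MIN_GENES = 550`, which sits in the valley between the planted
low-coverage sub-peak (libraries scaled to 15%) and the main coverage peak;
tests and the acceptance script use that constant. The cutoff is a
parameter everywhere — nothing in the code assumes the desk value.

## Over-dispersed gene selection

Dispersion is variance/mean of NE computed per gene across cells
(population variance); genes with zero mean are ineligible and a named
exclusion panel (by default the sex-specific genes, whose dispersion tracks
the animal's sex rather than the cell's subtype) is removed before ranking.
Ties break on the gene identifier so selection is deterministic.

## Embedding and density clustering

The selected genes are reduced by PCA to 10 components — the conventional
droplet-pipeline default; with ~10 well-separated populations the signal
subspace is essentially covered and most per-gene sampling noise is
discarded — and embedded by 3-D Barnes-Hut t-SNE with its classic defaults
(perplexity 30, 1000 gradient iterations, PCA initialization, fixed seed).
DBSCAN runs in the 3-D embedding with eps = 5.0 and minpts = 15; noise
points become cluster 0 ("fits no subtype uniquely") and clusters are
renumbered 1..K by decreasing size (ties by the original label). DBSCAN on
all three t-SNE dimensions, rather than two, was chosen because the third
dimension demonstrably separates subtypes that overlap in any 2-D view.

Contaminant screening: a round-1 cluster is flagged when its mean NE over
the contaminant (non-RGC) marker panel exceeds its mean NE over the pan-RGC
panel — an operationalization of "highly expresses non-RGC markers" that
needs no tuned threshold. Flagged cells are excluded, the gene set
re-derived, and round 2 produces the final labels. When nothing is flagged
the round-1 result is returned unchanged (identical input reproduces it).

## Unique markers

A gene is a unique marker of cluster k when its mean NE in k exceeds its
mean NE in every other cluster by strictly more than `fold_thr` (1.8) and
its home mean exceeds `min_ne` (0.05). Folds are ratios of mean NE values
(log-scale units); a linear-scale variant (de-logged means) exists behind a
flag. A zero denominator counts as enriched when the home mean clears the
floor. For the top `top_n_tested` (5) fold-ranked candidates per cluster,
per-comparison Welch t-tests (two-tailed; the R default flavour of the
independent-samples t-test) and two-sided Mann–Whitney U tests give tier
labels from the worst-case p over the K−1 comparisons: strict (both ≤
0.05), relaxed (t ≤ 0.05, MWU ≤ 0.1), weak (exactly one ≤ 0.05, the other >
0.1). No multiple-testing correction is applied by default, matching the
per-comparison thresholds the tiering is defined with; clusters smaller
than a configurable size emit markers with a small-cluster caveat flag
rather than being suppressed.

## Homogeneity census

At each threshold τ a gene participates when its maximum cluster mean NE
exceeds τ; it is homogeneous when max/min cluster mean ≤ 1.5 (zero minimum
with positive maximum → non-homogeneous). Counts and within-category
percentages (relative to the > 0 NE baseline of the same TF/non-TF ×
homogeneous/non-homogeneous category) are reported; counts are monotone
non-increasing in τ by construction.

## Laterality

The 2×K eye × cluster table excludes unknown-eye cells and, by default,
cluster 0. The global test is Pearson χ² (df = K−1). Per cluster, the
share of left-eye cells belonging to it is compared with the right-eye
share by a pooled two-proportion z-test (statsmodels), Bonferroni-multiplied
across the K clusters; clusters with fewer than two cells or a degenerate
pooled proportion are reported untestable. For K = 2 the z² equals the χ²
statistic, asserted numerically in the tests. Mirror symmetry compares
Pearson correlations of eye-specific mean-NE profiles: same-cluster
left/right pairs versus all ordered cross-cluster pairs, with a two-sample
t-test between the two sets. The per-cluster percentage correlation
(`eye_proportion_correlation`) is defined for K ≥ 2 (two points give ±1)
and returns NaN under zero variance.

## Hierarchy and ISPs

The subtype tree is Ward linkage over Chebyshev (maximum-coordinate)
distances between cluster mean-NE profiles; maximum distance + complete
linkage is available for the flat-heatmap style dendrogram. Cutting one
tree at two maxclust levels yields superclusters and ISPs that are nested
by construction; group ids are renumbered by smallest member cluster, and
cuts that cannot realize the requested count (tied heights) are flagged
ambiguous rather than silently accepted. ISP-level enrichment applies the
unique-marker rule to cell-weighted ISP-merged profiles and then verifies
each candidate in every member cluster against every non-member cluster,
dropping genes carried by only part of the ISP — the automated form of a
per-cluster confirmation step.

## TF combinatorics

Binarization: TF t is "enriched" in cluster k iff mean NE > 0.5 and > 2×
the unweighted mean of t's cluster means (cluster-level profiles justify
the unweighted mean). Rows all-one or all-zero are dropped with an audit
list. Subsets up to `max_k` (≤ 5) are enumerated in increasing size,
lexicographic within size; a subset whose AND pattern lights exactly one
cluster is a signature, and minimality (no unique proper subset for the
same cluster) resolves "unique as a combination but not individually" —
supersets of a unique subset necessarily collapse to the same cluster, so
pruning them is exact (verified against a pruning-free exhaustive oracle).
Cross-referencing repeats the search at a relaxed 1.5× fold and keeps
combinations found identically under both thresholds. Statistical support
is the TF × cluster interaction of a pingouin mixed-design ANOVA
(TF within-cell, cluster between-cells, sphericity assumed): `p_focal`
averages the interaction p over focal-vs-other comparisons and
`p_between_others` over all non-focal pairs; single-TF signatures return
NaN (no interaction to test). How the source statistics suite laid out this
ANOVA is not fully specified anywhere; the mixed-design reading is this
package's choice, and exact agreement with any particular statistics suite's p-value
table is not claimed.

## Synthetic data

The generator draws gamma-Poisson (negative binomial, dispersion θ = 8)
counts with per-cell log-normal size factors (σ = 0.12) from a hierarchical
mean model and returns the full planted truth. Structure and rationale:

- **Hierarchy**: background genes get multiplicative log-normal offsets at
  supercluster (σ = 0.65), ISP (σ = 0.55) and cluster (σ = 0.05) levels, so
  within-ISP profiles correlate more than across-ISP ones. The cluster
  level is kept small because, at low expression, NE-fold ≈ linear fold:
  wide per-cluster offsets would mass-produce genuine unique markers that
  are not in the planted marker map.
- **Separation program genes** (600 by default): each enriched
  (8-fold from a 0.4–0.7 baseline) in exactly two clusters from different
  ISPs. They emulate the many non-unique subtype-program genes that carry
  most of the real separation between subtypes, can never satisfy the
  all-vs-every unique-marker rule, and stay below the cross-ISP scale of
  the maximum-distance tree metric.
- **Markers**: fixed 0.2-count baseline × `marker_fold` in the home cluster
  only. The baseline is deliberately low — the NE-scale fold of a linear
  2.5× enrichment shrinks as the baseline grows, and at 0.2 counts the
  expected NE fold (~2.3) clears the 1.8 threshold with margin.
- **Background baselines** are bimodal (30% silent at 0.002, the rest
  log-normal clipped ≥ 0.2): genes in the intermediate band would sit near
  the 0.05 NE floor where ratio noise at a few hundred cells per cluster
  produces spurious unique-marker calls.
- **Cluster profiles are depth-equalized** by rescaling the background
  block so every cluster has the same total expression: systematic library
  depth differences between subtypes would otherwise shift all NE values of
  a cluster and distort every planted fold.
- **TF combinations**: for an m-way combination, m distinct decoy clusters
  d₁..d_m are drawn and member i is "on" in the target plus every decoy
  except d_i — the intersection is exactly the target, every proper subset
  still shares a decoy (non-trivial minimality), and no member is unique.
  On-levels (2.35→2.2 NE) are anti-ordered against off-levels (0.06→0.28
  NE), giving each member a distinct dynamic range, as co-enriched factors
  have in real programs; this makes the member profiles non-parallel in
  every focal comparison (a detectable interaction) while non-focal,
  non-decoy clusters remain mutually parallel (the null contrast).
- **Eye, sex, QC, contaminants**: eye labels are Bernoulli per cluster
  (default 0.5); sex is Bernoulli per cell and drives three sex-specific
  genes (strongly over-dispersed, hence the exclusion panel); 6% of cells
  have size factors scaled to 0.15 (the low-coverage sub-peak); 4% of cells
  are contaminants drawn from a permuted baseline profile with the
  contaminant panel high and the RGC panel low.

Problem sizes: the test-suite's study conditions are 3000 cells × 2000
genes × 8 clusters in 4 ISPs under 2 superclusters (`desk_config`); marker
precision/recall is evaluated at 8000 cells of the same design, where
cluster-mean estimates are tight enough for the max-over-others fold
statistic to separate planted 2.5-fold markers from the 1.8 threshold
reliably. `SimConfig` defaults describe the full-scale design (6000 cells ×
5000 genes × 40 clusters / 10 ISPs / 4 superclusters).

What passing tests show — and what they do not: the generator produces
well-separated, roughly spherical expression clusters with independent
genes within a cluster. Real data add doublets, ambient RNA, batch effects,
gene–gene correlation within subtype, and continuous (non-discrete)
variation; recovery results here certify the implementation, not
performance guarantees on arbitrary tissue.

## Numerical choices

- Degenerate inputs are errors, not warnings: zero-total cells, empty
  clusters, unresolvable panels, all-cells-removed QC.
- Dispersion and census ties break on gene identifier; DBSCAN renumbering
  ties break on the original label; ISP renumbering uses the smallest
  member cluster — all outputs are deterministic for a fixed seed,
  including byte-identical pipeline artifacts.
- Fold with a zero denominator is "satisfied" (∞) only when the home mean
  clears the expression floor.
- p-values are held at full precision internally; the human-readable
  pipeline outputs round to 4 decimals.

## Known limitations

- DBSCAN's eps is in embedding units; t-SNE's global scale varies with cell
  count and implementation, so the eps = 5.0 default is validated for the
  desk-scale conditions and should be re-examined on very different sizes.
- The mixed-design interaction ANOVA is one reading of an under-specified
  procedure (see above).
- `two_round` performs one exclusion round, as the analysis it implements
  does; repeated-until-clean iteration is not provided.
- The laterality z-test uses the pooled-variance two-proportion form; other
  variance conventions exist and differ slightly at small counts.
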