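"""Subtype dendrogram, supercluster/ISP cuts and ISP-level enrichment.

The diversification hierarchy is read off an agglomerative tree over the
cluster mean-NE profiles (Chebyshev a.k.a. maximum distance, Ward linkage by
default; maximum distance + complete linkage available for the flat-heatmap
style dendrogram).  Horizontal cuts of the same tree at two depths yield the
superclusters and the intermediate subpopulations (ISPs), which are nested
by construction.

ISP-level enrichment first merges the member clusters of each ISP into one
pseudo-cluster and applies the unique-marker fold rule on the merged
profiles, then verifies each candidate gene cluster-by-cluster — it must be
enriched over every non-ISP cluster in every member cluster individually —
dropping candidates carried by only part of the ISP.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .clustering import ClusterResult
from .io import GenePanel
from .markers import ClusterProfile, _min_fold


class HierarchyError(ValueError):
    pass


@dataclass
class SubtypeTree:
    linkage_matrix: np.ndarray
    leaves: list[int]  # cluster ids in leaf index order
    metric: str
    method: str


@dataclass
class ISPAssignment:
    cluster_to_isp: dict[int, int]
    isp_to_supercluster: dict[int, int]
    prevalence: pd.Series  # fraction of clustered cells per ISP
    ambiguous: bool = False

    def members(self, isp: int) -> list[int]:
        return sorted(k for k, i in self.cluster_to_isp.items() if i == isp)


def build_tree(
    prof: ClusterProfile, metric: str = "chebyshev", method: str = "ward"
) -> SubtypeTree:
    """Agglomerate the K cluster mean-NE columns into a dendrogram."""
    if len(prof.clusters) < 2:
        raise HierarchyError("need at least 2 clusters to build a tree")
    X = prof.mean_ne.to_numpy().T  # clusters x genes
    dist = pdist(X, metric=metric)
    Z = linkage(dist, method=method)
    return SubtypeTree(
        linkage_matrix=Z, leaves=list(prof.clusters), metric=metric, method=method
    )


def cut_isps(
    tree: SubtypeTree,
    prof: ClusterProfile,
    n_super: int = 4,
    n_isp: int = 10,
) -> ISPAssignment:
    """Cut the tree into ``n_super`` superclusters and ``n_isp`` nested ISPs.

    Group ids are renumbered deterministically by their smallest member
    cluster.  Tied merge heights can make a maxclust cut return fewer groups
    than requested; the result is then flagged ambiguous.
    """
    K = len(tree.leaves)
    if not 1 <= n_super <= n_isp <= K:
        raise HierarchyError("require 1 <= n_super <= n_isp <= K")
    raw_isp = fcluster(tree.linkage_matrix, t=n_isp, criterion="maxclust")
    raw_sup = fcluster(tree.linkage_matrix, t=n_super, criterion="maxclust")
    ambiguous = len(set(raw_isp)) != n_isp or len(set(raw_sup)) != n_super

    def renumber(raw: np.ndarray) -> dict[int, int]:
        by_group: dict[int, int] = {}
        for leaf, g in zip(tree.leaves, raw):
            by_group.setdefault(int(g), leaf)
        order = sorted(by_group, key=lambda g: by_group[g])
        remap = {g: i + 1 for i, g in enumerate(order)}
        return {leaf: remap[int(g)] for leaf, g in zip(tree.leaves, raw)}

    cl_to_isp = renumber(raw_isp)
    cl_to_sup = renumber(raw_sup)
    isp_to_sup: dict[int, int] = {}
    for k, isp in cl_to_isp.items():
        sup = cl_to_sup[k]
        if isp in isp_to_sup and isp_to_sup[isp] != sup:
            raise HierarchyError("cuts are not nested")  # cannot happen on one tree
        isp_to_sup[isp] = sup
    sizes = prof.n_cells
    total = float(sizes.sum())
    prev = pd.Series(
        {
            isp: float(sum(sizes[k] for k, i in cl_to_isp.items() if i == isp)) / total
            for isp in sorted(set(cl_to_isp.values()))
        },
        name="prevalence",
    )
    return ISPAssignment(
        cluster_to_isp=cl_to_isp,
        isp_to_supercluster=isp_to_sup,
        prevalence=prev,
        ambiguous=ambiguous,
    )


def isp_enriched(
    adata_ne: ad.AnnData,
    cr: ClusterResult,
    prof: ClusterProfile,
    isps: ISPAssignment,
    fold_thr: float = 1.8,
    min_ne: float = 0.05,
    verify_per_cluster: bool = True,
    tfs: GenePanel | None = None,
) -> dict[int, pd.DataFrame]:
    """Genes uniquely enriched at the ISP level, verified per member cluster.

    Returns, per ISP, a frame of genes that (a) pass the unique-enrichment
    fold rule on the ISP-merged mean profiles against every other ISP, and
    (b) when ``verify_per_cluster`` is on, are enriched over every non-ISP
    *cluster* in every member cluster individually.  The ``is_tf`` column
    marks members of the TF panel when one is given.
    """
    M = prof.mean_ne
    sizes = prof.n_cells
    isp_ids = sorted(set(isps.cluster_to_isp.values()))
    # cell-weighted merged means: ISP mean = weighted average of member means
    merged = {}
    for isp in isp_ids:
        members = isps.members(isp)
        w = np.array([sizes[k] for k in members], dtype=float)
        merged[isp] = (M[members].to_numpy() * w).sum(axis=1) / w.sum()
    merged_df = pd.DataFrame(merged, index=M.index)
    genes = M.index.to_numpy()
    tf_set: set[str] = set()
    if tfs is not None:
        present, _ = tfs.resolve(genes)
        tf_set = set(present)
    out: dict[int, pd.DataFrame] = {}
    for isp in isp_ids:
        home = merged_df[isp].to_numpy()
        others = merged_df.drop(columns=isp).to_numpy()
        mf = _min_fold(home, others, min_ne)
        cand = np.flatnonzero((mf > fold_thr) & (home > min_ne))
        keep = []
        members = isps.members(isp)
        non_member = [k for k in prof.clusters if k not in members]
        for gi in cand:
            ok = True
            if verify_per_cluster and non_member:
                other_means = M.loc[genes[gi], non_member].to_numpy()
                for k in members:
                    hv = float(M.loc[genes[gi], k])
                    f = _min_fold(np.array([hv]), other_means[None, :], min_ne)[0]
                    if not (f > fold_thr and hv > min_ne):
                        ok = False
                        break
            if ok:
                keep.append(gi)
        out[isp] = pd.DataFrame(
            {
                "gene": [str(genes[i]) for i in keep],
                "min_fold_merged": [float(mf[i]) for i in keep],
                "mean_ne": [float(home[i]) for i in keep],
                "is_tf": [str(genes[i]) in tf_set for i in keep],
            }
        )
    return out


def to_newick(tree: SubtypeTree) -> str:
    """Serialize the dendrogram as a newick string with cluster-id leaves."""
    root = to_tree(tree.linkage_matrix)
    leaves = tree.leaves

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"c{leaves[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(root, root.dist) + ";"
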