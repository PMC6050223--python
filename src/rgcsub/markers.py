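"""Cluster expression profiles, unique subtype markers and the gene census.

A gene is a *unique marker* of a subtype when its mean NE there exceeds its
mean NE in every other cluster by more than a fold threshold (default 1.8,
strict inequality) and it is expressed above a floor (default 0.05 NE).  For
the top fold-ranked candidates per cluster, per-comparison Welch t-tests and
Mann-Whitney U tests on the per-cell NE values grade each marker into tiers:

    strict   both tests p <= 0.05 in every comparison
    relaxed  t <= 0.05 and MWU <= 0.1
    weak     exactly one test <= 0.05 while the other is > 0.1

The homogeneity census counts, across expression thresholds, genes expressed
within a 1.5-fold band between any two clusters (homogeneous — cell-type
level genes) versus genes exceeding that band somewhere (non-homogeneous —
subtype-differentiating genes), separately for TFs and other genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .clustering import ClusterResult
from .io import GenePanel


class MarkerError(ValueError):
    pass


@dataclass
class ClusterProfile:
    """Per-cluster mean and median NE (genes x clusters, clusters 1..K)."""

    mean_ne: pd.DataFrame
    median_ne: pd.DataFrame
    n_cells: pd.Series

    @property
    def clusters(self) -> list[int]:
        return [int(c) for c in self.mean_ne.columns]


@dataclass
class MarkerRecord:
    gene: str
    cluster: int
    min_fold: float
    expr: float
    p_t_max: float | None = None
    p_mwu_max: float | None = None
    tier: str | None = None
    small_cluster: bool = False


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def profile(adata_ne: ad.AnnData, cr: ClusterResult) -> ClusterProfile:
    """Mean and median NE per gene per cluster (cluster 0 excluded)."""
    K = cr.n_clusters
    if K < 1:
        raise MarkerError("no clusters (K = 0)")
    sub = adata_ne[cr.barcodes]
    X = _dense(sub.X)
    means, medians, sizes = {}, {}, {}
    for k in range(1, K + 1):
        cells = cr.members(k)
        if cells.size == 0:
            raise MarkerError(f"cluster {k} is empty")
        block = X[cells]
        means[k] = block.mean(axis=0)
        medians[k] = np.median(block, axis=0)
        sizes[k] = int(cells.size)
    idx = pd.Index(sub.var_names, name="gene")
    return ClusterProfile(
        mean_ne=pd.DataFrame(means, index=idx),
        median_ne=pd.DataFrame(medians, index=idx),
        n_cells=pd.Series(sizes, name="n_cells"),
    )


def _min_fold(home: np.ndarray, others: np.ndarray, min_ne: float) -> np.ndarray:
    """Minimum fold of home mean NE vs each other cluster, treating a zero
    denominator as satisfied (fold = inf) when the home mean clears the floor."""
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = home[:, None] / others
    folds = np.where(others == 0, np.where(home[:, None] > min_ne, np.inf, 0.0), folds)
    return folds.min(axis=1)


def unique_markers(
    adata_ne: ad.AnnData,
    cr: ClusterResult,
    prof: ClusterProfile,
    fold_thr: float = 1.8,
    min_ne: float = 0.05,
    top_n_tested: int = 5,
    small_cluster_size: int = 20,
) -> list[MarkerRecord]:
    """Uniquely enriched genes per cluster with dual-test tiering.

    Per-cell significance tests are run only for the ``top_n_tested``
    fold-ranked candidates per cluster; the remaining passing genes are
    emitted untested (tier ``None``).  Clusters smaller than
    ``small_cluster_size`` cells emit their markers with a small-cluster
    caveat instead of being suppressed.
    """
    if fold_thr <= 0 or min_ne < 0:
        raise MarkerError("thresholds must be positive")
    K = cr.n_clusters
    if K < 2:
        raise MarkerError("fold enrichment undefined with fewer than 2 clusters")
    sub = adata_ne[cr.barcodes]
    X = _dense(sub.X)
    M = prof.mean_ne.to_numpy()
    genes = prof.mean_ne.index.to_numpy()
    records: list[MarkerRecord] = []
    for ki, k in enumerate(prof.clusters):
        home = M[:, ki]
        others = np.delete(M, ki, axis=1)
        mf = _min_fold(home, others, min_ne)
        passing = np.flatnonzero((mf > fold_thr) & (home > min_ne))
        if passing.size == 0:
            continue
        order = passing[np.argsort(-mf[passing], kind="stable")]
        small = int(prof.n_cells[k]) < small_cluster_size
        in_k = cr.labels == k
        for rank, gi in enumerate(order):
            rec = MarkerRecord(
                gene=str(genes[gi]),
                cluster=k,
                min_fold=float(mf[gi]),
                expr=float(home[gi]),
                small_cluster=small,
            )
            if rank < top_n_tested:
                vals_k = X[in_k, gi]
                p_t, p_u = [], []
                for kj in prof.clusters:
                    if kj == k:
                        continue
                    vals_o = X[cr.labels == kj, gi]
                    p_t.append(stats.ttest_ind(vals_k, vals_o, equal_var=False).pvalue)
                    p_u.append(stats.mannwhitneyu(vals_k, vals_o,
                                                  alternative="two-sided").pvalue)
                rec.p_t_max = float(np.max(p_t))
                rec.p_mwu_max = float(np.max(p_u))
                rec.tier = _tier(rec.p_t_max, rec.p_mwu_max)
            records.append(rec)
    return records


def _tier(p_t: float, p_u: float) -> str | None:
    if p_t <= 0.05 and p_u <= 0.05:
        return "strict"
    if p_t <= 0.05 and p_u <= 0.1:
        return "relaxed"
    if (p_t <= 0.05) != (p_u <= 0.05) and max(p_t, p_u) > 0.1:
        return "weak"
    return None


def markers_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "cluster": r.cluster,
                "min_fold": r.min_fold,
                "expr": r.expr,
                "p_t_max": r.p_t_max,
                "p_mwu_max": r.p_mwu_max,
                "tier": r.tier,
                "small_cluster": r.small_cluster,
            }
            for r in records
        ]
    )


def homogeneity_census(
    prof: ClusterProfile,
    tfs: GenePanel | None,
    thresholds: list[float],
    fold_band: float = 1.5,
) -> pd.DataFrame:
    """Counts of homogeneous vs non-homogeneous genes across NE thresholds.

    A gene enters the census at threshold tau when its maximum cluster mean
    NE exceeds tau; it is homogeneous when max/min cluster mean <= fold_band
    (a zero minimum with a positive maximum is non-homogeneous).  Percentages
    are normalized within each (TF / non-TF) x (homogeneous / not) category
    to its count of genes expressed > 0 NE.
    """
    if sorted(thresholds) != list(thresholds):
        raise MarkerError("thresholds must be sorted ascending")
    M = prof.mean_ne.to_numpy()
    names = prof.mean_ne.index.to_numpy()
    mx, mn = M.max(axis=1), M.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mn > 0, mx / np.where(mn > 0, mn, 1.0), np.inf)
    homog = (mx > 0) & (ratio <= fold_band)
    if tfs is not None:
        present, _ = tfs.resolve(names)
        is_tf = np.isin(names, list(present))
    else:
        is_tf = np.zeros(len(names), dtype=bool)
    rows = []
    for tf_flag, tf_name in ((True, "tf"), (False, "gene")):
        if tf_flag and tfs is None:
            continue
        sel = is_tf == tf_flag
        for homog_flag, homog_name in ((True, "homogeneous"), (False, "non_homogeneous")):
            base = int(((mx > 0) & sel & (homog == homog_flag)).sum())
            for tau in thresholds:
                cnt = int(((mx > tau) & sel & (homog == homog_flag)).sum())
                rows.append(
                    {
                        "category": tf_name,
                        "homogeneity": homog_name,
                        "threshold": tau,
                        "count": cnt,
                        "pct": 100.0 * cnt / base if base else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def cluster_correlations(prof: ClusterProfile) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson r between cluster mean-NE profiles and each cluster's mean r.

    Zero-variance profiles yield missing correlations.  The returned series
    is sorted ascending (least to most similar cluster).
    """
    if len(prof.clusters) < 2:
        raise MarkerError("need at least 2 clusters")
    corr = prof.mean_ne.corr(method="pearson")
    np.fill_diagonal(corr.values, np.nan)
    mean_r = corr.mean(axis=1, skipna=True).sort_values()
    mean_r.name = "mean_r"
    return corr, mean_r


def zscore_rows(prof: ClusterProfile) -> pd.DataFrame:
    """Row-wise z-scored mean NE, the heatmap-ready export."""
    M = prof.mean_ne
    mu = M.mean(axis=1)
    sd = M.std(axis=1, ddof=0).replace(0.0, np.nan)
    return M.sub(mu, axis=0).div(sd, axis=0)
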