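"""Left/right-eye representation of subtypes and mirror-symmetry statistics.

The eye x cluster contingency table is tested globally with Pearson's chi2
(df = K - 1 for two eyes) and per cluster with two-sided two-proportion
z-tests of the cluster's share of each eye's cells, Bonferroni-adjusted
across clusters.  Mirror symmetry of the transcriptomes is quantified by
comparing Pearson correlations of eye-specific cluster profiles: same
cluster across eyes versus different clusters across eyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .clustering import ClusterResult


class LateralityError(ValueError):
    pass


@dataclass
class EyeClusterTable:
    """2 x K counts of cells per eye per cluster (rows: left, right)."""

    counts: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def clusters(self) -> list[int]:
        return [int(c) for c in self.counts.columns]


def build_table(
    cr: ClusterResult,
    eye: pd.Series | None = None,
    adata: ad.AnnData | None = None,
    include_cluster0: bool = False,
) -> EyeClusterTable:
    """Tabulate cells per eye per cluster.

    ``eye`` is a barcode-indexed series of "left"/"right"/"unknown"; it can
    be taken from ``adata.obs["eye"]``.  Unknown-eye cells are dropped, and
    cluster-0 (unassigned) cells are excluded unless requested.
    """
    if eye is None:
        if adata is None:
            raise LateralityError("provide eye labels or an AnnData with obs['eye']")
        eye = adata.obs["eye"]
    eye = eye.reindex(cr.barcodes).astype(str)
    labels = cr.labels
    known = eye.isin(["left", "right"]).to_numpy()
    if not known.any():
        raise LateralityError("no cells with a known eye of origin")
    mask = known if include_cluster0 else (known & (labels > 0))
    ks = sorted({int(k) for k in np.unique(labels[mask])})
    table = pd.DataFrame(0, index=["left", "right"], columns=ks, dtype=int)
    for e in ("left", "right"):
        sel = mask & (eye.to_numpy() == e)
        vals, cnts = np.unique(labels[sel], return_counts=True)
        for v, c in zip(vals, cnts):
            table.loc[e, int(v)] = int(c)
    if (table.sum(axis=1) == 0).any():
        raise LateralityError("one eye has no cells in the table")
    return EyeClusterTable(counts=table)


def chi_square(t: EyeClusterTable) -> tuple[float, int, float]:
    """Pearson chi-squared over the 2 x K table; df = K - 1."""
    c = t.counts.to_numpy()
    if (c.sum(axis=1) == 0).any() or (c.sum(axis=0) == 0).any():
        raise LateralityError("zero row or column total")
    stat, p, df, expected = stats.chi2_contingency(c, correction=False)
    if (expected == 0).any():
        raise LateralityError("zero expected count")
    return float(stat), int(df), float(p)


def column_proportion_tests(
    t: EyeClusterTable,
    alpha: float = 0.001,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-cluster two-proportion z-tests of left vs right representation.

    For each cluster the proportion of left-eye cells that belong to it is
    compared with the proportion of right-eye cells that belong to it
    (pooled-variance z).  p-values are Bonferroni-multiplied across the K
    clusters unless ``correction`` is "none".  Clusters too small to test
    (fewer than 2 cells, or a degenerate pooled proportion) are reported
    untestable and never flagged.
    """
    n_left, n_right = int(t.totals["left"]), int(t.totals["right"])
    K = len(t.clusters)
    rows = []
    for k in t.clusters:
        x_l, x_r = int(t.counts.loc["left", k]), int(t.counts.loc["right", k])
        total = x_l + x_r
        pooled = (x_l + x_r) / (n_left + n_right)
        if total < 2 or pooled in (0.0, 1.0):
            rows.append({"cluster": k, "left_pct": 100 * x_l / n_left,
                         "right_pct": 100 * x_r / n_right, "z": np.nan,
                         "p": np.nan, "p_adj": np.nan, "testable": False,
                         "significant": False, "enriched_eye": None})
            continue
        z, p = proportions_ztest([x_l, x_r], [n_left, n_right])
        p_adj = min(1.0, p * K) if correction == "bonferroni" else p
        sig = bool(p_adj < alpha)
        eye = None
        if sig:
            eye = "left" if x_l / n_left > x_r / n_right else "right"
        rows.append({"cluster": k, "left_pct": 100 * x_l / n_left,
                     "right_pct": 100 * x_r / n_right, "z": float(z),
                     "p": float(p), "p_adj": float(p_adj), "testable": True,
                     "significant": sig, "enriched_eye": eye})
    return pd.DataFrame(rows).set_index("cluster")


def eye_mirror_correlations(
    adata_ne: ad.AnnData,
    cr: ClusterResult,
    min_cells_per_eye: int = 2,
) -> tuple[list[float], list[float], float]:
    """Same-cluster vs cross-cluster correlations of eye-specific profiles.

    Builds a mean-NE profile per (cluster, eye); returns Pearson r for every
    same-cluster left/right pair, r for every ordered cross-cluster
    left/right pair, and the two-sample t-test p-value between the two sets.
    Clusters lacking ``min_cells_per_eye`` cells in either eye are skipped.
    """
    sub = adata_ne[cr.barcodes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    eye = sub.obs["eye"].astype(str).to_numpy()
    profiles: dict[int, dict[str, np.ndarray]] = {}
    for k in range(1, cr.n_clusters + 1):
        in_k = cr.labels == k
        pair = {}
        for e in ("left", "right"):
            cells = in_k & (eye == e)
            if cells.sum() < min_cells_per_eye:
                break
            pair[e] = X[cells].mean(axis=0)
        if len(pair) == 2:
            profiles[k] = pair
    if len(profiles) < 2:
        raise LateralityError("fewer than 2 clusters testable in both eyes")
    same = [
        float(stats.pearsonr(p["left"], p["right"])[0]) for p in profiles.values()
    ]
    diff = [
        float(stats.pearsonr(profiles[a]["left"], profiles[b]["right"])[0])
        for a in profiles
        for b in profiles
        if a != b
    ]
    t_p = float(stats.ttest_ind(same, diff).pvalue)
    return same, diff, t_p


def eye_proportion_correlation(t: EyeClusterTable) -> float:
    """Pearson r between per-cluster percentages of each eye's total cells.

    Measures how proportionally the subtypes are shared between the eyes;
    returns NaN when either percentage vector has zero variance.
    """
    if len(t.clusters) < 2:
        raise LateralityError("need at least 2 clusters")
    left = t.counts.loc["left"].to_numpy(dtype=float)
    right = t.counts.loc["right"].to_numpy(dtype=float)
    lp = 100 * left / left.sum()
    rp = 100 * right / right.sum()
    if np.std(lp) == 0 or np.std(rp) == 0:
        return float("nan")
    return float(stats.pearsonr(lp, rp)[0])
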