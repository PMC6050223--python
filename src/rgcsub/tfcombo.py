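"""Combinatorial search for TF signatures uniquely enriched in one subtype.

A TF is called "enriched" in a cluster when its mean NE there exceeds 0.5 NE
and more than a fold (2x by default) of the unweighted mean of its cluster
means, producing a TFs x clusters binary matrix (rows that are all ones or
all zeros carry no combinatorial information and are dropped).  All TF
subsets up to five members are enumerated; the AND of the member rows is the
combination's enrichment pattern, and patterns lighting up exactly one
cluster are unique signatures of that cluster.  A combination is kept only
if it is minimal — no proper subset is already unique for the same cluster —
capturing "unique as a combination but not individually".

Cross-referencing re-runs the search with a relaxed 1.5x fold and keeps only
combinations found identically under both thresholds, widening the gap
between the signature's home cluster and the next best match.

The statistical support for a combination is the TF x cluster interaction of
a mixed-design ANOVA (TF identity within-cell, cluster membership between
cells, sphericity assumed) comparing the focal cluster against each other
cluster; the same interaction among non-focal cluster pairs provides the
no-signal baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import pingouin as pg
import scipy.sparse as sp

from .clustering import ClusterResult
from .io import GenePanel
from .markers import ClusterProfile


class TFComboError(ValueError):
    pass


@dataclass
class TFBinaryMatrix:
    indicator: pd.DataFrame  # TFs x clusters, 0/1
    fold_threshold: float
    min_ne: float
    dropped: list[str]  # TFs whose rows were all-0 or all-1

    @property
    def tfs(self) -> list[str]:
        return [str(t) for t in self.indicator.index]


@dataclass
class TFComboRecord:
    cluster: int
    tfs: tuple[str, ...]
    unique: bool = True
    p_focal: float | None = None
    p_between_others: float | None = None


def binarize(
    prof: ClusterProfile,
    tfs: GenePanel,
    min_ne: float = 0.5,
    fold: float = 2.0,
) -> TFBinaryMatrix:
    """Threshold TF cluster means into the enrichment indicator matrix."""
    if min_ne <= 0 or fold <= 0:
        raise TFComboError("thresholds must be positive")
    present, _ = tfs.resolve(prof.mean_ne.index)
    if not present:
        raise TFComboError("TF panel resolves to zero genes in the profile")
    M = prof.mean_ne.loc[present]
    row_mean = M.mean(axis=1)  # unweighted mean over cluster means
    ind = ((M.gt(min_ne)) & (M.gt(fold * row_mean, axis=0))).astype(int)
    keep = (ind.sum(axis=1) > 0) & (ind.sum(axis=1) < ind.shape[1])
    dropped = [str(t) for t in ind.index[~keep]]
    return TFBinaryMatrix(
        indicator=ind.loc[keep], fold_threshold=fold, min_ne=min_ne, dropped=dropped
    )


def unique_combos(bm: TFBinaryMatrix, max_k: int = 5) -> list[TFComboRecord]:
    """Minimal TF subsets whose joint enrichment pattern is a single cluster.

    Enumerates subsets by increasing size, lexicographically within a size
    (following the row order of the binary matrix), so output order is
    deterministic.  A subset containing an already-unique smaller signature
    is skipped: the AND of a superset can only shrink the pattern, so such a
    superset would be unique for the same cluster and therefore non-minimal.
    """
    if not 1 <= max_k <= 5:
        raise TFComboError("max_k must be in 1..5")
    tf_names = bm.tfs
    rows = {t: bm.indicator.loc[t].to_numpy(dtype=bool) for t in tf_names}
    clusters = [int(c) for c in bm.indicator.columns]
    found: list[tuple[frozenset, int]] = []
    records: list[TFComboRecord] = []
    for k in range(1, max_k + 1):
        for combo in combinations(tf_names, k):
            cset = frozenset(combo)
            if any(prev < cset for prev, _ in found):
                continue  # a proper subset is already unique
            pattern = rows[combo[0]].copy()
            for t in combo[1:]:
                pattern &= rows[t]
            s = int(pattern.sum())
            if s == 1:
                cluster = clusters[int(np.flatnonzero(pattern)[0])]
                found.append((cset, cluster))
                records.append(TFComboRecord(cluster=cluster, tfs=tuple(combo)))
    return records


def cross_reference(
    prof: ClusterProfile,
    tfs: GenePanel,
    min_ne: float = 0.5,
    fold_strict: float = 2.0,
    fold_relaxed: float = 1.5,
    max_k: int = 5,
) -> list[TFComboRecord]:
    """Signatures surviving both the strict and the relaxed fold thresholds."""
    if not fold_relaxed < fold_strict:
        raise TFComboError("fold_relaxed must be below fold_strict")
    strict = unique_combos(binarize(prof, tfs, min_ne, fold_strict), max_k=max_k)
    relaxed = unique_combos(binarize(prof, tfs, min_ne, fold_relaxed), max_k=max_k)
    relaxed_keys = {(r.cluster, frozenset(r.tfs)) for r in relaxed}
    return [r for r in strict if (r.cluster, frozenset(r.tfs)) in relaxed_keys]


def _interaction_p(X: np.ndarray, labels: np.ndarray, gene_cols: list[int],
                   a: int, b: int) -> float:
    """TF x cluster interaction p (sphericity assumed) for clusters a vs b."""
    cells = np.flatnonzero((labels == a) | (labels == b))
    frames = []
    for gi, col in enumerate(gene_cols):
        frames.append(
            pd.DataFrame(
                {
                    "ne": X[cells, col],
                    "tf": gi,
                    "cell": cells,
                    "grp": labels[cells],
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    aov = pg.mixed_anova(
        data=long, dv="ne", within="tf", subject="cell", between="grp"
    )
    row = aov.loc[aov["Source"] == "Interaction"]
    return float(row["p_unc"].iloc[0])


def interaction_anova(
    adata_ne: ad.AnnData,
    cr: ClusterResult,
    combo: TFComboRecord,
    min_cells: int = 3,
) -> tuple[float, float]:
    """Mean interaction p of the combo's TFs: focal-vs-others and among others.

    For a combination of two or more TFs, each pairwise comparison fits a
    mixed-design ANOVA on per-cell NE of the member TFs (TF within-cell,
    cluster between-cells); the headline numbers are the mean TF x cluster
    interaction p over the focal-vs-other comparisons and over all pairs of
    non-focal clusters.  A single-TF signature has no interaction to test and
    returns (nan, nan).
    """
    if len(combo.tfs) < 2:
        return float("nan"), float("nan")
    sub = adata_ne[cr.barcodes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    name_to_col = {g: i for i, g in enumerate(sub.var_names)}
    try:
        cols = [name_to_col[t] for t in combo.tfs]
    except KeyError as exc:
        raise TFComboError(f"combo TF {exc} absent from the matrix") from exc
    labels = cr.labels
    usable = [
        k for k in range(1, cr.n_clusters + 1) if (labels == k).sum() >= min_cells
    ]
    if combo.cluster not in usable:
        raise TFComboError(f"focal cluster {combo.cluster} has fewer than {min_cells} cells")
    others = [k for k in usable if k != combo.cluster]
    if not others:
        raise TFComboError("no comparison clusters available")
    p_focal = float(
        np.mean([_interaction_p(X, labels, cols, combo.cluster, b) for b in others])
    )
    pair_ps = [
        _interaction_p(X, labels, cols, a, b) for a, b in combinations(others, 2)
    ]
    p_between = float(np.mean(pair_ps)) if pair_ps else float("nan")
    return p_focal, p_between


def combos_to_frame(records: list[TFComboRecord]) -> pd.DataFrame:
    width = max((len(r.tfs) for r in records), default=1)
    rows = []
    for r in records:
        row = {"cluster": r.cluster}
        for i in range(width):
            row[f"TF{i + 1}"] = r.tfs[i] if i < len(r.tfs) else ""
        row["p_focal"] = r.p_focal
        row["p_between_others"] = r.p_between_others
        rows.append(row)
    return pd.DataFrame(rows)
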