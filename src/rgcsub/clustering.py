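"""Two-round t-SNE embedding and DBSCAN subtype clustering.

Cells are embedded into three Barnes-Hut t-SNE dimensions computed from the
most over-dispersed genes, and subtypes are called by DBSCAN in that 3-D
space (eps = 5.0 embedding units, minpts = 15).  DBSCAN noise points become
cluster 0 — cells that do not fit uniquely into any one subtype — and real
clusters are renumbered 1..K by decreasing size.

A first clustering round is screened for contaminant (non-RGC) clusters by
comparing panel expression; cells of flagged clusters are excluded, the
over-dispersed gene set is re-derived on the remaining cells, and the second
round produces the final subtype assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io import GenePanel
from .preprocess import select_overdispersed


class ClusteringError(ValueError):
    pass


@dataclass
class Embedding:
    coords: np.ndarray  # cells x 3
    barcodes: list[str]
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    """Per-cell labels (0 = unassigned noise) over an embedding."""

    labels: np.ndarray
    embedding: Embedding
    round: int = 1

    @property
    def barcodes(self) -> list[str]:
        return self.embedding.barcodes

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def embed(
    adata_ne: ad.AnnData,
    genes: list[str],
    seed: int,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    pca_dims: int = 10,
) -> Embedding:
    """3-D Barnes-Hut t-SNE of the cells over the given gene subset.

    An initial PCA to ``pca_dims`` dimensions (10 principal components, the
    droplet-pipeline default; skipped when the input is already narrower or
    ``pca_dims`` is 0) precedes the Barnes-Hut t-SNE gradient with its
    classic defaults (perplexity 30, 1000 iterations).  Deterministic for a
    fixed seed.  Raises if there are too few cells for the perplexity
    (t-SNE requires n_cells > perplexity).
    """
    n_cells = adata_ne.n_obs
    required = int(perplexity) + 1
    if n_cells < required:
        raise ClusteringError(
            f"{n_cells} cells is too few for perplexity {perplexity}; "
            f"need at least {required}"
        )
    sub = adata_ne[:, genes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    if pca_dims and X.shape[1] > pca_dims:
        X = PCA(n_components=pca_dims, svd_solver="full").fit_transform(X)
    tsne = TSNE(
        n_components=3,
        perplexity=perplexity,
        max_iter=max_iter,
        method="barnes_hut",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        barcodes=adata_ne.obs_names.tolist(),
        seed=seed,
        params={
            "perplexity": perplexity,
            "max_iter": max_iter,
            "n_components": 3,
            "pca_dims": pca_dims,
        },
    )


def density_cluster(emb: Embedding, eps: float = 5.0, minpts: int = 15,
                    round: int = 1) -> ClusterResult:
    """DBSCAN over the 3-D embedding; noise -> 0, clusters renumbered by size."""
    if eps <= 0 or minpts < 1:
        raise ClusteringError("require eps > 0 and minpts >= 1")
    raw = DBSCAN(eps=eps, min_samples=minpts).fit_predict(emb.coords)
    labels = np.zeros_like(raw)
    uniq = [u for u in np.unique(raw) if u >= 0]
    # decreasing size; ties broken by the original DBSCAN label for determinism
    sizes = {u: int((raw == u).sum()) for u in uniq}
    for new, u in enumerate(sorted(uniq, key=lambda u: (-sizes[u], u)), start=1):
        labels[raw == u] = new
    return ClusterResult(labels=labels, embedding=emb, round=round)


def flag_contaminants(
    cr: ClusterResult,
    adata_ne: ad.AnnData,
    contaminant: GenePanel,
    rgc: GenePanel,
) -> set[int]:
    """Clusters whose mean NE over the contaminant panel beats the RGC panel.

    Operationalizes "outlier clusters highly expressing non-RGC markers":
    a cluster is flagged iff its panel-mean contaminant expression exceeds
    its panel-mean RGC-marker expression.
    """
    cont_genes, _ = contaminant.resolve(adata_ne.var_names)
    rgc_genes, _ = rgc.resolve(adata_ne.var_names)
    if not cont_genes or not rgc_genes:
        raise ClusteringError("a marker panel resolved to zero genes")
    sub = adata_ne[cr.barcodes]
    flagged: set[int] = set()
    for k in range(1, cr.n_clusters + 1):
        cells = cr.members(k)
        block_c = sub[cells, cont_genes].X
        block_r = sub[cells, rgc_genes].X
        mean_c = float(block_c.mean())
        mean_r = float(block_r.mean())
        if mean_c > mean_r:
            flagged.add(k)
    return flagged


def two_round(
    adata_ne: ad.AnnData,
    contaminant: GenePanel,
    rgc: GenePanel,
    seed: int,
    n_dispersed: int = 1000,
    exclude: GenePanel | None = None,
    eps: float = 5.0,
    minpts: int = 15,
    perplexity: float = 30.0,
    max_iter: int = 1000,
) -> tuple[ClusterResult, list[str], float]:
    """Cluster, drop contaminant clusters, re-select genes and re-cluster.

    Returns the final :class:`ClusterResult`, the excluded barcodes, and the
    excluded percentage of all round-1 cells.  When round 1 flags nothing the
    round-1 result is returned unchanged (identical input would reproduce it
    exactly).
    """
    genes1 = select_overdispersed(adata_ne, n=n_dispersed, exclude=exclude)
    emb1 = embed(adata_ne, genes1, seed=seed, perplexity=perplexity, max_iter=max_iter)
    cr1 = density_cluster(emb1, eps=eps, minpts=minpts, round=1)
    flagged = flag_contaminants(cr1, adata_ne, contaminant, rgc)
    excluded = [b for b, lab in zip(cr1.barcodes, cr1.labels) if lab in flagged]
    pct = excluded_fraction(len(excluded), adata_ne.n_obs)
    if not flagged:
        cr1.round = 2
        return cr1, [], pct
    keep = [b for b in adata_ne.obs_names if b not in set(excluded)]
    sub = adata_ne[keep].copy()
    genes2 = select_overdispersed(sub, n=n_dispersed, exclude=exclude)
    emb2 = embed(sub, genes2, seed=seed, perplexity=perplexity, max_iter=max_iter)
    cr2 = density_cluster(emb2, eps=eps, minpts=minpts, round=2)
    return cr2, excluded, pct


def excluded_fraction(n_excluded: int, n_round1: int) -> float:
    """Excluded cells as a percentage of all round-1 cells (one decimal place
    is how it is conventionally reported; full precision returned)."""
    if n_round1 <= 0:
        raise ClusteringError("n_round1 must be positive")
    return 100.0 * n_excluded / n_round1
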