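"""Quality filtering, NE normalization and over-dispersed gene selection.

NE ("normalized expression") is the unit every downstream threshold is stated
in: each cell's counts are scaled by M / T_c, where T_c is the cell's total
transcript count and M the median of those totals across cells, and then
log2-transformed after a +1 pseudocount:

    NE_gc = log2( x_gc * M / T_c + 1 )

Zero counts therefore map exactly to NE 0, and within a cell NE is a strictly
increasing function of the count.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .io import GenePanel


class PreprocessError(ValueError):
    pass


def genes_detected(adata: ad.AnnData) -> np.ndarray:
    """Number of genes with count > 0 per cell."""
    X = adata.X
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def filter_low_coverage(
    adata: ad.AnnData, min_genes: int = 3000
) -> tuple[ad.AnnData, list[str]]:
    """Drop cells detecting fewer than ``min_genes`` genes.

    Removes the low-coverage sub-peak of barcodes whose shallow libraries
    would add noise downstream.  Returns the retained matrix and the list of
    removed barcodes for audit.  Raises if the cutoff removes every cell.
    """
    if min_genes < 0:
        raise PreprocessError("min_genes must be >= 0")
    det = genes_detected(adata)
    keep = det >= min_genes
    if not keep.any():
        raise PreprocessError(
            f"min_genes={min_genes} removes all {adata.n_obs} cells "
            f"(max detected: {det.max() if len(det) else 0})"
        )
    removed = adata.obs_names[~keep].tolist()
    return adata[keep].copy(), removed


def normalize_ne(adata: ad.AnnData) -> ad.AnnData:
    """Median-of-totals library-size normalization with log2(x+1).

    Returns a new AnnData whose X holds NE values; the scaling constant M and
    source totals are recorded under ``.uns["ne"]`` for provenance.  A cell
    with zero total counts is an error (it cannot be scaled) and is reported
    by barcode.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if np.any(totals <= 0):
        bad = adata.obs_names[totals <= 0][0]
        raise PreprocessError(f"cell {bad!r} has zero total counts")
    M = float(np.median(totals))  # even n: mean of the two middle values
    scale = M / totals
    if sp.issparse(X):
        ne = X.multiply(scale[:, None]).tocsr()
        ne.data = np.log2(ne.data + 1.0)
    else:
        ne = np.log2(np.asarray(X) * scale[:, None] + 1.0)
    out = ad.AnnData(X=ne, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.uns["ne"] = {"M": M, "n_source_cells": int(adata.n_obs)}
    return out


def select_overdispersed(
    adata_ne: ad.AnnData,
    n: int = 1000,
    exclude: GenePanel | None = None,
) -> list[str]:
    """The ``n`` genes with the largest variance/mean of NE.

    Genes with zero mean NE are ineligible; genes in ``exclude`` (e.g. the
    sex-specific panel, whose dispersion tracks the animal's sex rather than
    the cell's subtype) are removed before ranking.  Ties break by gene
    identifier.  If fewer than ``n`` genes are eligible all of them are
    returned with a warning.
    """
    if n < 1:
        raise PreprocessError("n must be >= 1")
    X = adata_ne.X
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = sq - mean**2
    else:
        Xd = np.asarray(X)
        mean = Xd.mean(axis=0)
        var = Xd.var(axis=0)
    names = np.asarray(adata_ne.var_names, dtype=object)
    eligible = mean > 0
    if exclude is not None:
        present, _ = exclude.resolve(names)
        eligible &= ~np.isin(names, list(present))
    disp = np.where(eligible, var / np.where(mean > 0, mean, 1.0), -np.inf)
    order = sorted(np.flatnonzero(eligible), key=lambda i: (-disp[i], names[i]))
    if len(order) < n:
        warnings.warn(
            f"only {len(order)} eligible genes for n={n}; returning all",
            stacklevel=2,
        )
        return [str(names[i]) for i in order]
    return [str(names[i]) for i in order[:n]]
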