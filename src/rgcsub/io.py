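"""Readers for 10x-style MatrixMarket count triplets and gene panels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class CountMatrixError(ValueError):
    """Malformed or inconsistent count-matrix input."""


@dataclass(frozen=True)
class GenePanel:
    """A named list of genes with a fixed role in the analysis."""

    name: str
    genes: tuple[str, ...]
    role: str  # rgc_marker | contaminant_marker | tf | sex

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    def resolve(self, gene_ids) -> tuple[list[str], list[str]]:
        """Split the panel into genes present in / missing from ``gene_ids``."""
        known = set(map(str, gene_ids))
        present = [g for g in self.genes if g in known]
        missing = [g for g in self.genes if g not in known]
        return present, missing


def read_panel(path, name: str | None = None, role: str = "tf") -> GenePanel:
    """Read a one-gene-per-line text file into a :class:`GenePanel`."""
    p = Path(path)
    genes = tuple(
        line.strip() for line in p.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    return GenePanel(name=name or p.stem, genes=genes, role=role)


def read_counts(mtx_path, genes_path, barcodes_path) -> ad.AnnData:
    """Read a genes x cells MatrixMarket triplet into a cells x genes AnnData.

    The MTX file follows the 10x orientation (genes as rows).  ``genes.tsv``
    holds one gene per line (first column used); ``barcodes.tsv`` holds the
    barcode with an optional second column naming the eye of origin
    (left/right; anything else, or absence, becomes "unknown").

    Raises :class:`CountMatrixError` on dimension mismatches (including an
    apparently transposed matrix), duplicate identifiers, or negative counts.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # malformed header or body
        raise CountMatrixError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc

    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    gene_ids = genes_df[0].tolist()
    bc_df = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    barcodes = bc_df[0].tolist()
    if bc_df.shape[1] >= 2:
        eye = bc_df[1].fillna("unknown").tolist()
    else:
        eye = ["unknown"] * len(barcodes)
    eye = [e if e in ("left", "right") else "unknown" for e in eye]

    n_genes, n_cells = mat.shape
    if (n_genes, n_cells) != (len(gene_ids), len(barcodes)):
        if (n_cells, n_genes) == (len(gene_ids), len(barcodes)):
            raise CountMatrixError(
                "matrix appears transposed (cells x genes); expected the 10x "
                "convention of genes as rows"
            )
        raise CountMatrixError(
            f"dimension mismatch: matrix is {n_genes} x {n_cells} but "
            f"{len(gene_ids)} genes and {len(barcodes)} barcodes were given"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise CountMatrixError("duplicate gene identifiers")
    if len(set(barcodes)) != len(barcodes):
        raise CountMatrixError("duplicate barcodes")

    X = sp.csr_matrix(mat.T)
    if X.nnz and X.data.min() < 0:
        raise CountMatrixError("negative count entries")
    adata = ad.AnnData(
        X=X.astype(np.int32),
        obs=pd.DataFrame(
            {"eye": pd.Categorical(eye, categories=["left", "right", "unknown"])},
            index=pd.Index(barcodes, name="barcode"),
        ),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    return adata
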