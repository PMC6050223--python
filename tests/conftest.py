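"""Shared fixtures: one desk-scale simulation reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import rgcsub as rs
from rgcsub.io import GenePanel

SEED = 11


@pytest.fixture(scope="session")
def desk_sim():
    cfg = rs.desk_config(seed=SEED)
    counts, truth = rs.generate(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def panels(desk_sim):
    _, counts, _ = desk_sim
    p = counts.uns["panels"]
    return {
        "rgc": GenePanel("rgc", tuple(p["rgc_marker"]), "rgc_marker"),
        "contaminant": GenePanel("contaminant", tuple(p["contaminant_marker"]), "contaminant_marker"),
        "sex": GenePanel("sex", tuple(p["sex"]), "sex"),
        "tf": GenePanel("tf", tuple(p["tf"]), "tf"),
    }


@pytest.fixture(scope="session")
def qc_ne(desk_sim):
    """QC-filtered, NE-normalized expression matrix."""
    _, counts, _ = desk_sim
    filtered, _ = rs.filter_low_coverage(counts, rs.simulate.DESK_QC_MIN_GENES)
    return rs.normalize_ne(filtered)


def truth_cluster_result(adata_ne, truth):
    """ClusterResult built from planted labels on retained non-contaminant cells."""
    idx = {b: i for i, b in enumerate(truth.barcodes)}
    keep = [b for b in adata_ne.obs_names if truth.cell_cluster[idx[b]] > 0]
    labels = np.array([truth.cell_cluster[idx[b]] for b in keep])
    emb = rs.Embedding(coords=np.zeros((len(keep), 3)), barcodes=keep, seed=0)
    return adata_ne[keep].copy(), rs.ClusterResult(labels=labels, embedding=emb)


@pytest.fixture(scope="session")
def truth_clustered(qc_ne, desk_sim):
    _, _, truth = desk_sim
    return truth_cluster_result(qc_ne, truth)


@pytest.fixture(scope="session")
def truth_profile(truth_clustered):
    ne_t, crt = truth_clustered
    return rs.profile(ne_t, crt)


@pytest.fixture(scope="session")
def clustered(qc_ne, panels):
    """One full two-round t-SNE + DBSCAN run (expensive; shared)."""
    return rs.two_round(
        qc_ne, panels["contaminant"], panels["rgc"], seed=SEED, exclude=panels["sex"]
    )
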