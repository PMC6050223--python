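"""Synthetic UMI count matrices with planted subtype structure.

The generator emulates the structure a droplet scRNA-seq experiment on an
immunopanned retinal-ganglion-cell (RGC) preparation is assumed to have:

* terminal subtypes ("clusters") of unequal prevalence, nested inside
  intermediate subpopulations (ISPs), nested inside superclusters;
* per-cluster unique marker genes (expression raised by a linear fold in the
  home cluster only);
* transcription factors (TFs) enriched as *combinations*: every member of a
  planted combination is high in the target cluster and in decoy clusters,
  so that no member is unique on its own while the intersection of the
  members' enrichment patterns is exactly the target cluster;
* per-cluster left/right-eye imbalance;
* a low-coverage cell sub-peak (cells whose library size is scaled down so
  they fall below a genes-detected QC cutoff);
* a small fraction of contaminant (non-RGC) cells drawn from an unrelated
  expression profile enriched for a contaminant marker panel;
* sex-specific genes expressed by the cell's sex rather than its cluster
  (these are deliberately over-dispersed across cells and must be excluded
  from clustering, as in the real pipeline).

Counts are negative-binomial (gamma-Poisson) with per-cell log-normal size
factors. All randomness flows through one ``numpy.random.default_rng(seed)``,
so the same seed yields bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class SimulationError(ValueError):
    """Invalid simulation configuration."""


class ComboPlantingError(SimulationError):
    """A requested TF combination cannot be planted uniquely."""


# NE targets used when back-solving count means for planted TF patterns.
# "on" must clear both binarization thresholds (>0.5 NE and >2x the mean of
# cluster means) with margin; "off" levels stay below the 0.5 NE floor at
# either fold, so the pattern is identical under both thresholds.  Off
# levels are staggered across the members of a combination (as in real TF
# programs, where co-enriched factors sit at distinct baselines); this makes
# the member profiles non-parallel in every focal-versus-other comparison,
# giving the interaction ANOVA something to detect.  The on/off gap is kept
# below the ISP-offset scale so planted combos do not dominate the
# maximum-distance dendrogram.
_TF_NE_ON_RANGE = (2.35, 2.2)  # anti-ordered against the off levels
_TF_NE_OFF_RANGE = (0.06, 0.28)

# Hierarchical log-scale offset widths (superclusters > ISPs > clusters), the
# knob that makes within-ISP cluster profiles correlate more than across-ISP
# ones while keeping spurious per-cluster unique-marker calls rare.
_SIGMA_SUPER = 0.65
_SIGMA_ISP = 0.55
_SIGMA_CLUSTER = 0.05

#: Genes-detected QC cutoff on the desk-scale (2000-gene) simulation; sits in
#: the valley between the low-coverage sub-peak and the main coverage peak,
#: playing the role the 3000-genes cutoff plays on a full transcriptome.
DESK_QC_MIN_GENES = 550


def _ne_to_mean(ne: float) -> float:
    """Invert the NE transform for a unit size factor: mean count for a target NE."""
    return float(2.0**ne - 1.0)


@dataclass
class SimConfig:
    """Study conditions of one simulated experiment.

    Defaults describe the full-scale design (40 subtypes in 10 ISPs in 4
    superclusters); :func:`desk_config` returns the smaller configuration
    used throughout the test-suite.
    """

    n_cells: int = 6000
    n_genes: int = 5000
    n_superclusters: int = 4
    n_isps: int = 10
    n_clusters: int = 40
    cluster_proportions: np.ndarray | None = None
    right_eye_prob: np.ndarray | float = 0.5
    markers_per_cluster: int = 3
    marker_fold: float = 3.0
    isp_markers_per_isp: int = 2
    isp_marker_fold: float = 3.0
    # "separation program" genes: each enriched in exactly two clusters from
    # different ISPs.  They emulate the many non-unique subtype-program genes
    # of real data — the bulk of what separates subtypes in the embedding —
    # while never qualifying as unique markers.
    separation_pair_genes: int = 600
    pair_fold: float = 8.0
    tf_panel_size: int = 60
    planted_combos: Sequence[tuple[int, tuple[str, ...]]] = field(default_factory=tuple)
    nb_dispersion: float = 8.0
    size_factor_lognorm_sigma: float = 0.12
    low_quality_fraction: float = 0.06
    low_quality_scale: float = 0.15
    contaminant_fraction: float = 0.04
    seed: int = 0

    # -- derived panels -------------------------------------------------
    @property
    def tf_names(self) -> list[str]:
        return [f"Tf{i + 1:02d}" for i in range(self.tf_panel_size)]

    @property
    def rgc_panel(self) -> list[str]:
        return [f"Rgc{i + 1}" for i in range(6)]

    @property
    def contaminant_panel(self) -> list[str]:
        return [f"NonRgc{i + 1}" for i in range(6)]

    @property
    def sex_panel(self) -> list[str]:
        return ["SexY1", "SexY2", "SexX1"]

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
        else:
            # unequal prevalences, most to least abundant
            p = np.linspace(1.35, 0.65, self.n_clusters)
            p = p / p.sum()
        return p

    def right_probs(self) -> np.ndarray:
        if np.isscalar(self.right_eye_prob):
            return np.full(self.n_clusters, float(self.right_eye_prob))
        return np.asarray(self.right_eye_prob, dtype=float)

    def validate(self) -> None:
        if not (self.n_clusters >= self.n_isps >= self.n_superclusters >= 1):
            raise SimulationError(
                "require n_clusters >= n_isps >= n_superclusters >= 1, got "
                f"{self.n_clusters}/{self.n_isps}/{self.n_superclusters}"
            )
        p = self.proportions()
        if p.shape != (self.n_clusters,):
            raise SimulationError("cluster_proportions length != n_clusters")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p <= 0):
            raise SimulationError("cluster_proportions must be positive and sum to 1")
        rp = self.right_probs()
        if rp.shape != (self.n_clusters,) or np.any((rp < 0) | (rp > 1)):
            raise SimulationError("right_eye_prob must be probabilities, one per cluster")
        if self.marker_fold < 1:
            raise SimulationError("marker_fold must be >= 1")
        panel = set(self.tf_names)
        seen_tfs: set[str] = set()
        for cluster, tfs in self.planted_combos:
            if not 1 <= cluster <= self.n_clusters:
                raise SimulationError(f"combo target cluster {cluster} out of range")
            if not 1 <= len(tfs) <= 5:
                raise ComboPlantingError("combo size must be between 1 and 5 TFs")
            if not set(tfs) <= panel:
                raise ComboPlantingError(f"combo TFs {tfs} not all in the TF panel")
            if set(tfs) & seen_tfs:
                raise ComboPlantingError("a TF may participate in only one planted combo")
            seen_tfs |= set(tfs)
            if len(tfs) >= 2 and self.n_clusters < len(tfs) + 1:
                raise ComboPlantingError(
                    f"cannot plant a {len(tfs)}-way unique combo with only "
                    f"{self.n_clusters} clusters"
                )
        n_reserved = (
            self.tf_panel_size
            + len(self.rgc_panel)
            + len(self.contaminant_panel)
            + len(self.sex_panel)
            + self.n_clusters * self.markers_per_cluster
            + self.n_isps * self.isp_markers_per_isp
            + self.separation_pair_genes
        )
        if self.separation_pair_genes and self.n_isps < 2:
            raise SimulationError("separation pair genes need at least 2 ISPs")
        if self.n_genes < n_reserved + 50:
            raise SimulationError(
                f"n_genes={self.n_genes} too small for {n_reserved} structured genes"
            )


def desk_config(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale study conditions used by the test-suite.

    3000 cells x 2000 genes, 8 strongly separated subtypes nested 2-per-ISP
    in 4 ISPs under 2 superclusters, 5 unique markers per subtype at 2.5-fold,
    a 20-TF panel with one 1-way, one 2-way and one 3-way planted combination,
    6% low-coverage cells and 4% contaminants.
    """
    cfg = dict(
        n_cells=3000,
        n_genes=2000,
        n_superclusters=2,
        n_isps=4,
        n_clusters=8,
        markers_per_cluster=5,
        marker_fold=2.5,
        isp_markers_per_isp=2,
        separation_pair_genes=600,
        tf_panel_size=20,
        planted_combos=(
            (7, ("Tf01",)),
            (2, ("Tf02", "Tf03")),
            (5, ("Tf04", "Tf05", "Tf06")),
        ),
        low_quality_fraction=0.06,
        low_quality_scale=0.15,
        contaminant_fraction=0.04,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    cell_cluster: np.ndarray  # 1..K for RGCs, -1 for contaminants
    cell_isp: np.ndarray
    cell_supercluster: np.ndarray
    cell_eye: np.ndarray  # "left"/"right"
    barcodes: list[str]
    marker_map: dict[int, tuple[str, ...]]
    isp_marker_map: dict[int, tuple[str, ...]]
    combo_map: dict[int, tuple[str, ...]]
    cluster_to_isp: dict[int, int]
    isp_to_supercluster: dict[int, int]
    contaminant_cells: set[str]
    low_quality_cells: set[str]

    def to_json(self) -> str:
        payload = {
            "cell_cluster": self.cell_cluster.tolist(),
            "cell_isp": self.cell_isp.tolist(),
            "cell_supercluster": self.cell_supercluster.tolist(),
            "cell_eye": self.cell_eye.tolist(),
            "barcodes": self.barcodes,
            "marker_map": {str(k): list(v) for k, v in self.marker_map.items()},
            "isp_marker_map": {str(k): list(v) for k, v in self.isp_marker_map.items()},
            "combo_map": {str(k): list(v) for k, v in self.combo_map.items()},
            "cluster_to_isp": {str(k): v for k, v in self.cluster_to_isp.items()},
            "isp_to_supercluster": {str(k): v for k, v in self.isp_to_supercluster.items()},
            "contaminant_cells": sorted(self.contaminant_cells),
            "low_quality_cells": sorted(self.low_quality_cells),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            cell_cluster=np.asarray(d["cell_cluster"], dtype=int),
            cell_isp=np.asarray(d["cell_isp"], dtype=int),
            cell_supercluster=np.asarray(d["cell_supercluster"], dtype=int),
            cell_eye=np.asarray(d["cell_eye"], dtype=object),
            barcodes=list(d["barcodes"]),
            marker_map={int(k): tuple(v) for k, v in d["marker_map"].items()},
            isp_marker_map={int(k): tuple(v) for k, v in d["isp_marker_map"].items()},
            combo_map={int(k): tuple(v) for k, v in d["combo_map"].items()},
            cluster_to_isp={int(k): int(v) for k, v in d["cluster_to_isp"].items()},
            isp_to_supercluster={int(k): int(v) for k, v in d["isp_to_supercluster"].items()},
            contaminant_cells=set(d["contaminant_cells"]),
            low_quality_cells=set(d["low_quality_cells"]),
        )


def _nested_partition(n_items: int, n_groups: int) -> np.ndarray:
    """Group ids (1-based) for items 1..n_items split into contiguous chunks."""
    return np.array_split(np.arange(n_items), n_groups), None


def _chunk_assignment(n_items: int, n_groups: int) -> dict[int, int]:
    chunks = np.array_split(np.arange(1, n_items + 1), n_groups)
    out: dict[int, int] = {}
    for gid, chunk in enumerate(chunks, start=1):
        for item in chunk:
            out[int(item)] = gid
    return out


def _combo_patterns(
    combos: Sequence[tuple[int, tuple[str, ...]]],
    n_clusters: int,
    rng: np.random.Generator,
    proportions: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Binary on/off cluster pattern per combo-member TF.

    For an m-way combo targeting cluster k, pick m distinct decoy clusters
    d_1..d_m != k; member i is "on" in {k} plus every decoy except d_i.  The
    intersection of all members is then exactly {k}; every proper subset of
    members still shares at least one decoy, so no sub-combination (and no
    single member, for m >= 2) is unique — planting a non-trivially minimal
    signature.  Decoys are drawn from the more prevalent clusters when there
    is a choice, so the planted enrichment pattern does not ride on the
    noisiest cluster-mean estimates.
    """
    patterns: dict[str, np.ndarray] = {}
    for cluster, tfs in combos:
        m = len(tfs)
        k0 = cluster - 1
        if m == 1:
            pat = np.zeros(n_clusters, dtype=bool)
            pat[k0] = True
            patterns[tfs[0]] = pat
            continue
        others = np.setdiff1d(np.arange(n_clusters), [k0])
        if len(others) < m:
            raise ComboPlantingError(
                f"cluster count {n_clusters} too small to plant a {m}-way combo"
            )
        if proportions is not None and len(others) > m:
            order = others[np.argsort(-proportions[others], kind="stable")]
            pool = order[: max(m, int(np.ceil(0.6 * len(others))))]
        else:
            pool = others
        decoys = rng.choice(pool, size=m, replace=False)
        for i, tf in enumerate(tfs):
            pat = np.zeros(n_clusters, dtype=bool)
            pat[k0] = True
            pat[np.delete(decoys, i)] = True
            patterns[tf] = pat
    return patterns


def generate(config: SimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a count matrix and its planted truth from the configured model.

    Returns an :class:`anndata.AnnData` of cells x genes sparse UMI counts
    (``obs``: barcode index, ``eye`` column; ``var``: gene ids) plus the
    :class:`SyntheticTruth` describing every planted feature.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, G, n = config.n_clusters, config.n_genes, config.n_cells
    theta = config.nb_dispersion

    cluster_to_isp = _chunk_assignment(K, config.n_isps)
    isp_to_super = _chunk_assignment(config.n_isps, config.n_superclusters)

    # ---- gene layout ---------------------------------------------------
    tf_names = config.tf_names
    rgc_panel = config.rgc_panel
    cont_panel = config.contaminant_panel
    sex_panel = config.sex_panel
    marker_names = [
        f"Mk{k:02d}_{j + 1}"
        for k in range(1, K + 1)
        for j in range(config.markers_per_cluster)
    ]
    isp_marker_names = [
        f"IspMk{i:02d}_{j + 1}"
        for i in range(1, config.n_isps + 1)
        for j in range(config.isp_markers_per_isp)
    ]
    pair_names = [f"Pair{i + 1:04d}" for i in range(config.separation_pair_genes)]
    n_structured = (
        len(tf_names) + len(rgc_panel) + len(cont_panel) + len(sex_panel)
        + len(marker_names) + len(isp_marker_names) + len(pair_names)
    )
    bg_names = [f"Bg{i + 1:05d}" for i in range(G - n_structured)]
    gene_names = (tf_names + rgc_panel + cont_panel + sex_panel + marker_names
                  + isp_marker_names + pair_names + bg_names)
    gidx = {g: i for i, g in enumerate(gene_names)}

    # ---- per-cluster mean model (RGC cells) ----------------------------
    mu = np.zeros((G, K))

    # background genes: log-normal baselines with nested multiplicative offsets
    n_bg = len(bg_names)
    bg_rows = np.array([gidx[g] for g in bg_names])
    # bimodal baselines: a silent (dropout) fraction plus well-expressed
    # genes; the in-between micro-expression band would contribute nothing
    # but ratio noise at desk-scale cluster sizes
    base = np.clip(rng.lognormal(mean=np.log(1.0), sigma=0.9, size=n_bg), 0.2, 30.0)
    base[rng.random(n_bg) < 0.3] = 0.002
    off_super = rng.normal(0.0, _SIGMA_SUPER, size=(n_bg, config.n_superclusters))
    off_isp = rng.normal(0.0, _SIGMA_ISP, size=(n_bg, config.n_isps))
    off_clu = rng.normal(0.0, _SIGMA_CLUSTER, size=(n_bg, K))
    for k in range(1, K + 1):
        isp = cluster_to_isp[k]
        sup = isp_to_super[isp]
        log_off = off_super[:, sup - 1] + off_isp[:, isp - 1] + off_clu[:, k - 1]
        mu[bg_rows, k - 1] = base * np.exp(log_off)

    # pan-RGC and contaminant panels
    for g in rgc_panel:
        mu[gidx[g], :] = 8.0
    for g in cont_panel:
        mu[gidx[g], :] = 0.02

    # unique subtype markers: low baseline, raised by marker_fold at home
    # only (the NE-scale fold shrinks as the baseline grows, so baselines
    # stay low enough for the linear fold to survive the log transform)
    marker_map: dict[int, tuple[str, ...]] = {}
    for k in range(1, K + 1):
        names = [f"Mk{k:02d}_{j + 1}" for j in range(config.markers_per_cluster)]
        marker_map[k] = tuple(names)
        for g in names:
            b = 0.2
            mu[gidx[g], :] = b
            mu[gidx[g], k - 1] = b * config.marker_fold

    # ISP-level markers: raised in every member cluster of the ISP
    isp_marker_map: dict[int, tuple[str, ...]] = {}
    for i in range(1, config.n_isps + 1):
        names = [f"IspMk{i:02d}_{j + 1}" for j in range(config.isp_markers_per_isp)]
        isp_marker_map[i] = tuple(names)
        members = [k for k, ik in cluster_to_isp.items() if ik == i]
        for g in names:
            b = rng.uniform(0.3, 0.6)
            mu[gidx[g], :] = b
            for k in members:
                mu[gidx[g], k - 1] = b * config.isp_marker_fold

    # separation program genes: strong in one random cluster of each of two
    # different ISPs
    for g in pair_names:
        isp_a, isp_b = rng.choice(np.arange(1, config.n_isps + 1), size=2, replace=False)
        ka = int(rng.choice([k for k, i in cluster_to_isp.items() if i == isp_a]))
        kb = int(rng.choice([k for k, i in cluster_to_isp.items() if i == isp_b]))
        b = rng.uniform(0.4, 0.7)
        mu[gidx[g], :] = b
        mu[gidx[g], [ka - 1, kb - 1]] = b * config.pair_fold

    # TF panel: planted combo members follow back-solved binary patterns;
    # the remaining TFs split into homogeneous and mildly variable ones.
    patterns = _combo_patterns(config.planted_combos, K, rng, config.proportions())
    combo_map = {cluster: tuple(tfs) for cluster, tfs in config.planted_combos}
    on_lo, on_hi = _TF_NE_ON_RANGE
    off_lo, off_hi = _TF_NE_OFF_RANGE
    free_tfs = [t for t in tf_names if t not in patterns]
    for _, tfs in config.planted_combos:
        m = len(tfs)
        if m == 1:
            ons = [0.5 * (on_lo + on_hi)]
            offs = [0.5 * (off_lo + off_hi)]
        else:
            ons = np.linspace(on_lo, on_hi, m)
            offs = np.linspace(off_lo, off_hi, m)
        for t, on_ne, off_ne in zip(tfs, ons, offs):
            mu[gidx[t], :] = np.where(
                patterns[t], _ne_to_mean(float(on_ne)), _ne_to_mean(float(off_ne))
            )
    for j, t in enumerate(free_tfs):
        b = rng.lognormal(np.log(1.5), 0.5)
        if j % 2 == 0:  # homogeneous TFs (cell-type level)
            mu[gidx[t], :] = b
        else:  # heterogeneous but not uniquely enriched
            mu[gidx[t], :] = b * np.exp(rng.normal(0.0, 0.25, size=K))

    # equalize total expression across cluster profiles: systematic depth
    # differences between subtypes would otherwise shift every NE value of a
    # cluster and distort planted fold ratios.  Only the background block is
    # rescaled so the planted means stay exact.
    colsum = mu.sum(axis=0)
    bg_sum = mu[bg_rows].sum(axis=0)
    mu[bg_rows] *= (colsum.mean() - (colsum - bg_sum)) / bg_sum

    # ---- contaminant profile ------------------------------------------
    mu_cont = np.full(G, 0.05)
    mu_cont[bg_rows] = rng.permutation(base) * np.exp(rng.normal(0.0, 0.4, size=n_bg))
    for g in cont_panel:
        mu_cont[gidx[g]] = 8.0
    for g in rgc_panel:
        mu_cont[gidx[g]] = 0.05

    # ---- cells ---------------------------------------------------------
    props = config.proportions()
    right_p = config.right_probs()
    contaminant = rng.random(n) < config.contaminant_fraction
    clusters = np.where(
        contaminant, -1, rng.choice(np.arange(1, K + 1), size=n, p=props)
    )
    low_quality = (~contaminant) & (rng.random(n) < config.low_quality_fraction)
    eye_p = np.where(contaminant, 0.5, right_p[np.clip(clusters, 1, K) - 1])
    eye = np.where(rng.random(n) < eye_p, "right", "left")
    sex_male = rng.random(n) < 0.5

    size = rng.lognormal(0.0, config.size_factor_lognorm_sigma, size=n)
    size[low_quality] *= config.low_quality_scale

    # per-cell mean matrix (cells x genes)
    cell_mu = np.empty((n, G))
    rgc_mask = ~contaminant
    cell_mu[rgc_mask] = mu[:, clusters[rgc_mask] - 1].T
    cell_mu[contaminant] = mu_cont
    # sex genes depend on the cell, not the cluster
    for g in ("SexY1", "SexY2"):
        cell_mu[:, gidx[g]] = np.where(sex_male, 3.0, 0.0)
    cell_mu[:, gidx["SexX1"]] = np.where(sex_male, 0.05, 3.0)
    cell_mu *= size[:, None]

    lam = rng.gamma(shape=theta, scale=cell_mu / theta)
    counts = rng.poisson(lam)
    del lam, cell_mu

    barcodes = [f"cell{i + 1:05d}" for i in range(n)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame({"eye": pd.Categorical(eye, categories=["left", "right", "unknown"])},
                         index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene_id")),
    )
    adata.uns["panels"] = {
        "tf": list(tf_names),
        "rgc_marker": list(rgc_panel),
        "contaminant_marker": list(cont_panel),
        "sex": list(sex_panel),
    }

    cell_isp = np.where(clusters > 0, [cluster_to_isp.get(int(c), -1) for c in clusters], -1)
    cell_super = np.where(
        clusters > 0, [isp_to_super.get(int(i), -1) for i in cell_isp], -1
    )
    truth = SyntheticTruth(
        cell_cluster=clusters.astype(int),
        cell_isp=cell_isp.astype(int),
        cell_supercluster=cell_super.astype(int),
        cell_eye=eye.astype(object),
        barcodes=barcodes,
        marker_map=marker_map,
        isp_marker_map=isp_marker_map,
        combo_map=combo_map,
        cluster_to_isp=cluster_to_isp,
        isp_to_supercluster=isp_to_super,
        contaminant_cells={b for b, c in zip(barcodes, contaminant) if c},
        low_quality_cells={b for b, lq in zip(barcodes, low_quality) if lq},
    )
    return adata, truth


def synthetic_bulk(adata_ne: ad.AnnData, seed: int = 0, sigma: float = 0.2,
                   scale: float = 20.0) -> pd.Series:
    """FPKM-like bulk reference: per-gene mean NE with multiplicative noise.

    Emulates a bulk RNA-seq of the pooled population for concordance checks;
    it shares no sampling noise with any individual cell.
    """
    rng = np.random.default_rng(seed)
    X = adata_ne.X
    mean_ne = np.asarray(X.mean(axis=0)).ravel() if sp.issparse(X) else X.mean(axis=0)
    fpkm = scale * mean_ne * rng.lognormal(0.0, sigma, size=mean_ne.size)
    return pd.Series(fpkm, index=adata_ne.var_names, name="fpkm")


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(adata: ad.AnnData, truth: SyntheticTruth | None, out_dir) -> dict[str, Path]:
    """Write matrix.mtx (genes x cells), genes.tsv, barcodes.tsv and truth.json.

    The MatrixMarket file follows the 10x convention of genes as rows.  The
    barcodes file carries the eye of origin in its second column.  Output is
    deterministic for a given matrix, so fixtures are reproducible byte for
    byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    X = adata.X
    coo = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scipy.io.mmwrite(str(paths["matrix"]), coo, field="integer")
    paths["genes"].write_text("".join(f"{g}\t{g}\n" for g in adata.var_names))
    eyes = adata.obs["eye"].astype(str)
    paths["barcodes"].write_text(
        "".join(f"{b}\t{e}\n" for b, e in zip(adata.obs_names, eyes))
    )
    if truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(truth.to_json())
    return paths


def load_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def fixture_checksum(dir_path) -> str:
    """SHA-256 over the canonical fixture files, for reproducibility checks."""
    h = hashlib.sha256()
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        h.update(Path(dir_path, name).read_bytes())
    return h.hexdigest()
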