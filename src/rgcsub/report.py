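"""Validation statistics, bulk concordance and the end-to-end pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from . import clustering, hierarchy, laterality, markers, preprocess, simulate, tfcombo
from .io import GenePanel


class ReportError(ValueError):
    pass


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def predicted_positive_pct(
    adata_ne: ad.AnnData,
    cr: clustering.ClusterResult,
    gene: str,
    home_cluster: int,
    detect_thr: float = 0.0,
) -> tuple[float, float, float]:
    """Marker-positive accounting: home-cluster %, low-expressing %, total.

    ``pct_home`` is the home cluster's share of all retained cells (cluster 0
    included in the denominator), ``pct_other`` the share of cells outside
    the home cluster whose NE for ``gene`` exceeds ``detect_thr``, and
    ``pct_total`` their sum — the fraction of cells an in-situ probe for the
    marker is predicted to light up.
    """
    if gene not in adata_ne.var_names:
        raise ReportError(f"unknown gene {gene!r}")
    sub = adata_ne[cr.barcodes, [gene]]
    vals = np.asarray(sub.X.todense()).ravel() if sp.issparse(sub.X) else np.asarray(sub.X).ravel()
    n = len(cr.labels)
    in_home = cr.labels == home_cluster
    pct_home = 100.0 * in_home.sum() / n
    pct_other = 100.0 * ((~in_home) & (vals > detect_thr)).sum() / n
    return float(pct_home), float(pct_other), float(pct_home + pct_other)


def one_sample_t(mean: float, sd: float, n: int, mu0: float) -> tuple[float, float]:
    """Two-tailed one-sample t-test from summary statistics."""
    if n < 2:
        raise ReportError("n must be >= 2")
    if sd <= 0:
        raise ReportError("sd must be positive")
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bulk_concordance(
    adata_ne: ad.AnnData, bulk: pd.Series, min_fpkm: float = 1.0
) -> tuple[float, float]:
    """Pearson r between per-gene mean NE and a bulk RNA-seq reference.

    Genes below ``min_fpkm`` in the bulk table are excluded as noise before
    correlating; returns (r, two-tailed p).
    """
    X = adata_ne.X
    mean_ne = pd.Series(
        np.asarray(X.mean(axis=0)).ravel() if sp.issparse(X) else np.asarray(X).mean(axis=0),
        index=adata_ne.var_names,
    )
    shared = mean_ne.index.intersection(bulk.index)
    bulk_s = bulk.loc[shared]
    shared = shared[bulk_s.to_numpy() >= min_fpkm]
    if len(shared) < 3:
        raise ReportError("fewer than 3 shared genes above the FPKM floor")
    r, p = stats.pearsonr(mean_ne.loc[shared], bulk.loc[shared])
    return float(r), float(p)


@dataclass
class PipelineConfig:
    """Flat configuration of an end-to-end synthetic run."""

    seed: int = 0
    min_genes: int = simulate.DESK_QC_MIN_GENES
    n_dispersed: int = 1000
    eps: float = 5.0
    minpts: int = 15
    perplexity: float = 30.0
    fold_thr: float = 1.8
    min_ne: float = 0.05
    tf_min_ne: float = 0.5
    tf_fold: float = 2.0
    tf_fold_relaxed: float = 1.5
    max_k: int = 3
    n_super: int = 2
    n_isp: int = 4
    anova_max_combos: int = 5
    alpha: float = 0.001
    sim: dict = field(default_factory=dict)  # overrides passed to desk_config

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file (lines starting # ignored)."""
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        cfg = cls()
        for key, val in kv.items():
            if key.startswith("sim."):
                cfg.sim[key[4:]] = int(val) if val.isdigit() else float(val)
                continue
            if not hasattr(cfg, key):
                raise ReportError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            setattr(cfg, key, type(cur)(val) if not isinstance(cur, dict) else val)
        return cfg


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, Path]:
    """Simulate, QC, normalize, cluster, and run every downstream analysis.

    Writes CSV/TSV/JSON/newick artifacts plus a line-oriented log into
    ``out_dir`` and returns the artifact paths.  Deterministic for a fixed
    seed (the log carries timestamps; every data artifact is byte-stable).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"{datetime.now(timezone.utc).isoformat()} {msg}")

    def stage(name: str):
        log(f"stage {name}")
        return name

    paths: dict[str, Path] = {}
    try:
        name = stage("simulate")
        sim_overrides = dict(config.sim)
        cfg = simulate.desk_config(seed=config.seed, **sim_overrides)
        counts, truth = simulate.generate(cfg)
        paths.update(simulate.write_fixture(counts, truth, out / "fixture"))
        panels = counts.uns["panels"]
        rgc = GenePanel("rgc", tuple(panels["rgc_marker"]), "rgc_marker")
        cont = GenePanel("contaminant", tuple(panels["contaminant_marker"]), "contaminant_marker")
        sex = GenePanel("sex", tuple(panels["sex"]), "sex")
        tf_panel = GenePanel("tf", tuple(panels["tf"]), "tf")

        name = stage("qc")
        counts_f, removed = preprocess.filter_low_coverage(counts, config.min_genes)
        paths["removed_cells"] = out / "removed_low_coverage.txt"
        paths["removed_cells"].write_text("\n".join(removed) + ("\n" if removed else ""))
        log(f"qc removed {len(removed)} cells at min_genes={config.min_genes}")

        name = stage("normalize")
        ne = preprocess.normalize_ne(counts_f)
        log(f"normalize M={ne.uns['ne']['M']}")

        name = stage("cluster")
        cr, excluded, pct = clustering.two_round(
            ne, cont, rgc, seed=config.seed, n_dispersed=config.n_dispersed,
            exclude=sex, eps=config.eps, minpts=config.minpts,
            perplexity=config.perplexity,
        )
        paths["excluded_cells"] = out / "excluded_contaminants.txt"
        paths["excluded_cells"].write_text("\n".join(excluded) + ("\n" if excluded else ""))
        emb_df = pd.DataFrame(
            cr.embedding.coords, columns=["x", "y", "z"],
            index=pd.Index(cr.barcodes, name="barcode"),
        )
        emb_df["cluster"] = cr.labels
        paths["embedding"] = out / "embedding.tsv"
        emb_df.to_csv(paths["embedding"], sep="\t", float_format="%.6g")
        log(f"clustered K={cr.n_clusters}, excluded {len(excluded)} ({pct:.1f}%)")

        name = stage("markers")
        ne_cr = ne[cr.barcodes].copy()
        prof = markers.profile(ne_cr, cr)
        recs = markers.unique_markers(
            ne_cr, cr, prof, fold_thr=config.fold_thr, min_ne=config.min_ne
        )
        paths["markers"] = out / "markers.csv"
        markers.markers_to_frame(recs).to_csv(paths["markers"], index=False, float_format="%.6g")
        census = markers.homogeneity_census(
            prof, tf_panel, thresholds=[0.0, 0.2, 0.4, 0.8, 1.6]
        )
        paths["census"] = out / "census.csv"
        census.to_csv(paths["census"], index=False, float_format="%.6g")

        name = stage("laterality")
        table = laterality.build_table(cr, adata=ne_cr)
        paths["contingency"] = out / "eye_cluster_counts.csv"
        table.counts.to_csv(paths["contingency"])
        lat = laterality.column_proportion_tests(table, alpha=config.alpha)
        paths["laterality"] = out / "laterality.csv"
        lat.to_csv(paths["laterality"], float_format="%.6g")
        chi_stat, df, chi_p = laterality.chi_square(table)
        prop_r = laterality.eye_proportion_correlation(table)

        name = stage("hierarchy")
        tree = hierarchy.build_tree(prof)
        paths["tree"] = out / "subtype_tree.nwk"
        paths["tree"].write_text(hierarchy.to_newick(tree) + "\n")
        isps = hierarchy.cut_isps(tree, prof, n_super=config.n_super, n_isp=config.n_isp)
        paths["isp"] = out / "isp_assignment.csv"
        pd.DataFrame(
            {
                "cluster": sorted(isps.cluster_to_isp),
                "isp": [isps.cluster_to_isp[k] for k in sorted(isps.cluster_to_isp)],
                "supercluster": [
                    isps.isp_to_supercluster[isps.cluster_to_isp[k]]
                    for k in sorted(isps.cluster_to_isp)
                ],
            }
        ).to_csv(paths["isp"], index=False)
        enriched = hierarchy.isp_enriched(
            ne_cr, cr, prof, isps, fold_thr=config.fold_thr,
            min_ne=config.min_ne, tfs=tf_panel,
        )
        paths["isp_genes"] = out / "isp_enriched.csv"
        pd.concat(
            [df.assign(isp=isp) for isp, df in enriched.items()], ignore_index=True
        ).to_csv(paths["isp_genes"], index=False, float_format="%.6g")

        name = stage("tfcombos")
        combos = tfcombo.cross_reference(
            prof, tf_panel, min_ne=config.tf_min_ne,
            fold_strict=config.tf_fold, fold_relaxed=config.tf_fold_relaxed,
            max_k=config.max_k,
        )
        for rec in combos[: config.anova_max_combos]:
            if len(rec.tfs) >= 2:
                rec.p_focal, rec.p_between_others = tfcombo.interaction_anova(
                    ne_cr, cr, rec
                )
        paths["combos"] = out / "tf_combinations.csv"
        tfcombo.combos_to_frame(combos).to_csv(paths["combos"], index=False, float_format="%.4f")

        name = stage("report")
        bulk = simulate.synthetic_bulk(ne, seed=config.seed)
        bulk_r, bulk_p = bulk_concordance(ne, bulk)
        summary = {
            "seed": config.seed,
            "n_cells_input": int(counts.n_obs),
            "n_cells_qc": int(counts_f.n_obs),
            "n_cells_clustered": len(cr.barcodes),
            "n_clusters": cr.n_clusters,
            "excluded_contaminant_pct": round(pct, 4),
            "chi_square": {"stat": round(chi_stat, 4), "df": df, "p": chi_p},
            "eye_proportion_r": None if np.isnan(prop_r) else round(prop_r, 4),
            "bulk_concordance_r": round(bulk_r, 4),
            "n_marker_records": len(recs),
            "n_tf_combinations": len(combos),
            "config": {k: v for k, v in asdict(config).items()},
        }
        paths["summary"] = out / "summary.json"
        paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    except Exception as exc:
        log(f"FAILED at stage {name}: {exc}")
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    log("done")
    paths["log"] = out / "pipeline.log"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
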