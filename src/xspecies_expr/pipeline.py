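"""End-to-end orchestration of the comparative expression analysis.

Runs the stages in study order — normalisation, tissue classification,
expression phylogeny and PCA, pattern clustering with categorisation,
highly variable transcripts, per-set enrichment, interactome statistics,
and dN/dS analysis — from a single flat-key YAML config with fixed seeds.
Every stage writes a TSV plus a JSON sidecar recording its parameters and
seed; wall-clock timings and versions go to ``run.log`` only, so the data
outputs of two runs with the same config are byte-identical.

An optional transcription-factor id list re-runs the clustering and
network stages on that subset, mirroring TF-focused re-analysis.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import category_proportions, classify
from .cluster import categorise_clusters, cluster_membership_report, kmeans_cluster
from .datamodel import inverse_log_transform
from .enrich import enrichment_frame, hypergeometric_enrichment
from .evolution import ecdf_by_group, expression_omega_regression, flag_positive_selection, summarise_expression
from .io import (
    read_edge_list,
    read_expression_matrix,
    read_gmt,
    read_omega_table,
    write_expression_matrix,
)
from .network import (
    average_neighbours,
    cluster_pair_connectivity,
    clustering_coefficient,
    neighbourhood_degrees,
)
from .normalize import normalize_expression
from .phylo import bootstrap_support, pca_with_ellipses
from .trees import write_newick
from .variability import detect_highly_variable, variability_summary

__all__ = ["PipelineConfig", "run_pipeline", "validate_config"]


@dataclass
class PipelineConfig:
    expression: str = None
    meta: str = None
    orthologs: str = None  # optional file with one transcript id per line
    annotations: str = None  # optional GMT
    ppi_edges: str = None  # optional edge-list TSV
    omega: str = None  # optional 2-column TSV
    tf_id_list: str = None  # optional TF subset, one id per line
    seed: int = 1
    n_boot: int = 1000
    k: int = 15
    n_init: int = 20
    t_high: float = 3.5
    t_enr: float = 2.0
    t_ubi_low: float = -2.0
    t_tissue: float = 2.0
    t_lineage: float = 2.0
    hvg_confidence: float = 0.95
    hvg_mode: str = "ci"
    hvg_fraction: float = 0.05
    alpha: float = 0.05
    collapse_replicates: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**raw)
        for key in ("expression", "meta", "orthologs", "annotations", "ppi_edges", "omega", "tf_id_list"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, key, str(base / val))
        return cfg


def validate_config(cfg: PipelineConfig) -> list:
    """Diagnostics for an unrunnable config; empty list means runnable."""
    diags = []
    if cfg.expression is None or cfg.meta is None:
        diags.append("expression and meta paths are required")
    for key in ("expression", "meta", "orthologs", "annotations", "ppi_edges", "omega", "tf_id_list"):
        val = getattr(cfg, key)
        if val is not None and not Path(val).exists():
            diags.append(f"{key}: file not found: {val}")
    if cfg.k < 1:
        diags.append("k must be >= 1")
    if not (0 < cfg.hvg_confidence < 1):
        diags.append("hvg_confidence must be in (0, 1)")
    if cfg.expression and Path(cfg.expression).exists() and cfg.meta and Path(cfg.meta).exists():
        try:
            m = read_expression_matrix(cfg.expression, cfg.meta)
            if cfg.k > len(m.transcript_ids):
                diags.append(f"k={cfg.k} exceeds number of transcripts {len(m.transcript_ids)}")
        except ValueError as exc:
            diags.append(f"expression: {exc}")
    return diags


def _read_id_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


class _Stage:
    """Context manager: timing/logging plus parameter sidecar for a stage."""

    def __init__(self, run, name, params):
        self.run, self.name, self.params = run, name, params

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            self.run.log(f"stage {self.name} FAILED: {exc}")
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        dt = time.perf_counter() - self.t0
        self.run.log(f"stage {self.name} finished in {dt:.2f}s")
        sidecar = self.run.out_dir / f"{self.name}.params.json"
        with open(sidecar, "w") as fh:
            json.dump({"stage": self.name, "seed": self.run.cfg.seed, **self.params}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")


class _Run:
    def __init__(self, cfg, out_dir):
        self.cfg = cfg
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self._log = open(self.out_dir / "run.log", "w")
        self.log(f"xspecies-expr {__version__}")

    def log(self, msg):
        self._log.write(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {msg}\n")
        self._log.flush()

    def stage(self, name, **params):
        return _Stage(self, name, params)

    def close(self):
        self._log.close()


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute every configured stage; returns the run directory."""
    diags = validate_config(cfg)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))
    run = _Run(cfg, out_dir)
    out = run.out_dir
    try:
        with run.stage("load", expression=cfg.expression, meta=cfg.meta):
            m = read_expression_matrix(cfg.expression, cfg.meta)
            orth = _read_id_list(cfg.orthologs) if cfg.orthologs else None

        with run.stage("normalize", orthologs=cfg.orthologs):
            norm_rep, norm_cond, w = normalize_expression(m, orth)
            write_expression_matrix(norm_rep, out / "normalized.tsv")
            fac = pd.DataFrame({"condition": w.factors.index, "factor": w.factors.values,
                                "median": w.sample_medians.values})
            fac["global_mean"] = w.global_mean
            fac.to_csv(out / "factors.tsv", sep="\t", index=False, float_format="%.12g")
            pd.Series(w.reference_orthologs).to_csv(
                out / "reference_orthologs.tsv", sep="\t", index=False, header=False
            )

        norm_cond_linear = inverse_log_transform(norm_cond)
        with run.stage("classify", t_high=cfg.t_high, t_enr=cfg.t_enr, t_ubi_low=cfg.t_ubi_low):
            calls = classify(norm_cond_linear, t_high=cfg.t_high, t_enr=cfg.t_enr,
                             t_ubi_low=cfg.t_ubi_low)
            calls.to_csv(out / "calls.tsv", sep="\t", index=False, float_format="%.12g")
            props = category_proportions(calls)
            props.to_csv(out / "category_proportions.tsv", sep="\t", float_format="%.12g")

        with run.stage("phylo", n_boot=cfg.n_boot):
            for tissue in norm_rep.tissues:
                tree = bootstrap_support(
                    norm_rep.subset_tissue(tissue), ("species",), cfg.n_boot, cfg.seed
                )
                write_newick(tree, out / f"tree_{tissue}.nwk")

        with run.stage("pca"):
            pca = pca_with_ellipses(norm_rep)
            pca.scores.round(10).to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.12g")
            pd.Series(pca.explained_variance_fraction, name="explained_fraction").to_csv(
                out / "pca_variance.tsv", sep="\t", index_label="component",
                float_format="%.12g",
            )

        with run.stage("cluster", k=cfg.k, n_init=cfg.n_init):
            cm = kmeans_cluster(norm_rep, k=cfg.k, seed=cfg.seed, n_init=cfg.n_init,
                                collapse_replicates=cfg.collapse_replicates)
            cm = categorise_clusters(cm, t_tissue=cfg.t_tissue, t_lineage=cfg.t_lineage)
            report = cluster_membership_report(cm)
            report.to_csv(out / "clusters.tsv", sep="\t")
            cm.centroids.round(10).to_csv(out / "centroids.tsv", sep="\t", float_format="%.12g")

        hvg_sets = {}
        with run.stage("hvg", confidence=cfg.hvg_confidence, mode=cfg.hvg_mode):
            norm_rep_linear = inverse_log_transform(norm_rep)
            for tissue in norm_rep.tissues:
                vt = detect_highly_variable(
                    norm_rep_linear.subset_tissue(tissue), confidence=cfg.hvg_confidence,
                    mode=cfg.hvg_mode, fraction=cfg.hvg_fraction,
                )
                vt.table.round(10).to_csv(out / f"hvg_{tissue}.tsv", sep="\t",
                                          index_label="transcript_id", float_format="%.12g")
                hvg_sets[tissue] = set(vt.highly_variable_ids)
                n_hv, frac = variability_summary(vt)
                run.log(f"hvg[{tissue}]: {n_hv} flagged ({100 * frac:.1f}%)")

        gene_sets = {f"cluster_{c}": cm.members(c) for c in range(cm.k)}
        gene_sets.update({f"hvg_{t}": s for t, s in hvg_sets.items() if s})

        if cfg.annotations:
            with run.stage("enrich", alpha=cfg.alpha):
                terms = read_gmt(cfg.annotations)
                universe = set(norm_rep.transcript_ids)
                frames = []
                for name, sel in sorted(gene_sets.items()):
                    if not sel:
                        continue
                    res = hypergeometric_enrichment(sel, universe, terms, alpha=cfg.alpha)
                    if res:
                        df = enrichment_frame(res)
                        df.insert(0, "gene_set", name)
                        frames.append(df)
                enr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.12g")

        if cfg.ppi_edges:
            with run.stage("netstats"):
                graph = read_edge_list(cfg.ppi_edges)
                clusters_in_graph = {
                    name: {v for v in sel if v in graph.nx}
                    for name, sel in gene_sets.items()
                }
                clusters_in_graph = {n: s for n, s in clusters_in_graph.items() if s}
                rows = []
                for name, sel in sorted(clusters_in_graph.items()):
                    cs = clustering_coefficient(graph, sel)
                    rows.append({
                        "gene_set": name,
                        "n_in_graph": len(sel),
                        "avg_clustering": cs.average_clustering,
                        "avg_neighbours": average_neighbours(graph, sel),
                    })
                pd.DataFrame(rows).to_csv(out / "network_sets.tsv", sep="\t", index=False,
                                          float_format="%.12g")
                conn = cluster_pair_connectivity(graph, clusters_in_graph)
                pairs = pd.DataFrame(
                    [(a, b, v) for (a, b), v in sorted(conn.pair_connectivity.items())],
                    columns=["set_a", "set_b", "connectivity"],
                )
                pairs.to_csv(out / "network_pairs.tsv", sep="\t", index=False,
                             float_format="%.12g")

        if cfg.omega:
            with run.stage("evolution"):
                om = read_omega_table(cfg.omega)
                avail = set(om.transcript_ids)
                groups = {n: {i for i in s if i in avail}
                          for n, s in gene_sets.items()}
                groups = {n: s for n, s in groups.items() if len(s) >= 3}
                ecdf = ecdf_by_group(om, groups) if groups else None
                expr_summary = summarise_expression(inverse_log_transform(norm_rep))
                reg = expression_omega_regression(om, expr_summary, groups)
                rows = []
                for name, r in sorted(reg.regression.items()):
                    ks = ecdf.ks_statistic.get(name) if ecdf else None
                    rows.append({"gene_set": name, **r,
                                 "ks_vs_background": "" if ks is None else ks})
                pd.DataFrame(rows).to_csv(out / "evolution.tsv", sep="\t", index=False,
                                          float_format="%.12g")
                pos = flag_positive_selection(om)
                pd.Series(sorted(pos)).to_csv(out / "positive_selection.tsv", sep="\t",
                                              index=False, header=False)

        if cfg.tf_id_list:
            with run.stage("tf_subset"):
                tf_ids = [t for t in _read_id_list(cfg.tf_id_list)
                          if t in set(norm_rep.transcript_ids)]
                run.log(f"tf subset: {len(tf_ids)} of listed TFs present")
                if len(tf_ids) >= 2:
                    k_tf = min(cfg.k, len(tf_ids))
                    cm_tf = kmeans_cluster(norm_rep.subset_transcripts(tf_ids), k=k_tf,
                                           seed=cfg.seed, n_init=cfg.n_init)
                    cm_tf = categorise_clusters(cm_tf, t_tissue=cfg.t_tissue,
                                                t_lineage=cfg.t_lineage)
                    cluster_membership_report(cm_tf).to_csv(out / "tf_clusters.tsv", sep="\t")
                    if cfg.ppi_edges:
                        graph = read_edge_list(cfg.ppi_edges)
                        tf_in_graph = [t for t in tf_ids if t in graph.nx]
                        if tf_in_graph:
                            deg = neighbourhood_degrees(graph, tf_in_graph)
                            pd.DataFrame({
                                "relation": ["first_degree", "second_degree"],
                                "count": [len(deg["first_degree"]), len(deg["second_degree"])],
                                "members": [",".join(sorted(deg["first_degree"])),
                                            ",".join(sorted(deg["second_degree"]))],
                            }).to_csv(out / "tf_network.tsv", sep="\t", index=False)
        run.log("pipeline complete")
    finally:
        run.close()
    return out
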