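"""Single-config orchestration of the full analysis.

Stage order: low-abundance filter -> log2 -> QQ diagnostics -> moderated
differential analysis over the three contrasts -> restored classification
-> DE enrichment -> CV filter -> permutation co-expression network ->
edge-betweenness modules -> module enrichment and reversal tests ->
knowledge-network comparison. Every threshold is echoed into the run
report, all randomness flows from the single config seed (stage-local
seeds are derived by stable hashing of the stage name), and outputs are
plain TSV/JSON so that re-running with the same config and seed
reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protcoex import communities, diffexp, enrichment, knowledge, network, preprocess
from protcoex.io import (
    AbundanceMatrix,
    GeneSetCollection,
    read_abundance_table,
    read_edge_list,
    read_gmt,
    read_id_map,
    write_edge_list,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, thresholds (study defaults) and the mandatory seed."""

    abundance_path: str | None = None
    meta_path: str | None = None
    gmt_path: str | None = None
    knowledge_edges_path: str | None = None
    pathway_genes_path: str | None = None
    id_map_path: str | None = None
    min_count: float = 1.0
    min_cv: float = 0.01
    p_max: float = 0.01
    lfc_min: float = 0.5
    n_perm: int = 50
    z_min: float = 1.5
    w_min: float = 0.5
    module_min_size: int = 10
    reversal_alpha: float = 0.05
    enrich_alpha: float = 0.05
    knowledge_min_score: float = 0.4
    community_backend: str = "igraph"
    seed: int | None = None
    outdir: str = "protcoex_run"
    write_qq_plots: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory in the pipeline config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def thresholds(self) -> dict:
        keys = (
            "min_count", "min_cv", "p_max", "lfc_min", "n_perm", "z_min",
            "w_min", "module_min_size", "reversal_alpha", "enrich_alpha",
            "knowledge_min_score", "seed",
        )
        return {k: getattr(self, k) for k in keys}


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _fail(stage: str, exc: Exception):
    raise StageError(f"stage '{stage}' failed: {exc}") from exc


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    matrix: AbundanceMatrix | None = None,
    collection: GeneSetCollection | None = None,
    knowledge_table: pd.DataFrame | None = None,
    pathway_genes: list[str] | None = None,
    id_map: dict[str, str] | None = None,
) -> dict:
    """Execute the full analysis and return (and write) the run report.

    Inputs may be passed as in-memory objects or read from the paths in
    the config; in-memory objects take precedence. Enrichment and the
    knowledge comparison run only when their inputs are available.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": config.thresholds()}

    # --- load ---
    if matrix is None:
        if config.abundance_path is None or config.meta_path is None:
            _fail("load", ValueError("no abundance matrix given (object or paths)"))
        try:
            matrix = read_abundance_table(config.abundance_path, config.meta_path)
        except Exception as exc:
            _fail("load", exc)
    if collection is None and config.gmt_path:
        try:
            collection = read_gmt(config.gmt_path)
        except Exception as exc:
            _fail("load_gene_sets", exc)
    if id_map is None and config.id_map_path:
        id_map = dict(read_id_map(config.id_map_path))

    # --- filters and transform ---
    try:
        filtered, low_report = preprocess.filter_low_abundance(matrix, config.min_count)
        log2_matrix = preprocess.log2_transform(filtered)
    except Exception as exc:
        _fail("low_abundance_filter", exc)
    report["low_abundance_filter"] = low_report.to_dict()
    logger.info("stage low_abundance_filter: %d -> %d proteins",
                low_report.n_input, low_report.n_output)

    try:
        qq = preprocess.qq_normality_check(
            log2_matrix, outdir=outdir if config.write_qq_plots else None
        )
        qq.to_csv(outdir / "qq_normality.tsv", sep="\t", float_format="%.6g")
    except Exception as exc:
        _fail("qq_diagnostics", exc)

    # --- differential analysis ---
    try:
        fit = diffexp.fit_condition_means(log2_matrix)
        mfit = diffexp.moderate_variances(fit)
        contrasts = {
            name: diffexp.compute_contrast(mfit, name)
            for name in diffexp.CANONICAL_CONTRASTS
        }
    except Exception as exc:
        _fail("differential_expression", exc)
    de_sets = {
        name: diffexp.call_de(res, config.p_max, config.lfc_min)
        for name, res in contrasts.items()
    }
    restored = diffexp.classify_restored(contrasts, config.p_max, config.lfc_min)
    for name, res in contrasts.items():
        table = res.table.copy()
        table["de"] = table.index.isin(de_sets[name])
        table.index.name = "protein"
        # log2fc orientation: A_vs_B = mean(A) - mean(B)
        table.to_csv(outdir / f"contrast_{name}.tsv", sep="\t", float_format="%.6g")
    report["differential_expression"] = {
        "d0": mfit.d0 if np.isfinite(mfit.d0) else "inf",
        "s0_sq": mfit.s0_sq,
        "de_counts": {name: len(s) for name, s in de_sets.items()},
        "de_union": len(set().union(*de_sets.values())),
        "restored": sorted(restored),
    }
    logger.info("stage differential_expression: DE counts %s, %d restored",
                report["differential_expression"]["de_counts"], len(restored))

    # --- DE enrichment ---
    if collection is not None:
        try:
            de_union = set().union(*de_sets.values())
            de_enrich = enrichment.enrich_de_proteins(
                de_union, collection, log2_matrix.protein_ids
            )
            de_enrich.to_csv(outdir / "de_enrichment.tsv", sep="\t",
                             index=False, float_format="%.6g")
            report["de_enrichment"] = {
                "n_sets_tested": int(len(de_enrich)),
                "n_significant": int((de_enrich["p"] <= config.enrich_alpha).sum()),
            }
        except Exception as exc:
            _fail("de_enrichment", exc)

    # --- co-expression network ---
    try:
        cv_matrix, cv_report = preprocess.cv_filter(filtered, config.min_cv)
        net_input = preprocess.log2_transform(cv_matrix)
        ids, W = network.pairwise_abs_pearson(net_input)
        _, Z = network.permutation_zscores(
            net_input, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "permutation_zscores"),
        )
        provenance = {"n_perm": config.n_perm, "seed": config.seed}
        net = network.threshold_network(ids, W, Z, config.z_min, config.w_min, provenance)
    except Exception as exc:
        _fail("coexpression_network", exc)
    report["cv_filter"] = cv_report.to_dict()
    report["coexpression_network"] = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "provenance": net.provenance,
    }
    write_edge_list(net.edge_records(), outdir / "coexpression_edges.tsv")
    logger.info("stage coexpression_network: %d nodes, %d edges", net.n_nodes, net.n_edges)

    # --- communities ---
    try:
        moduleset = communities.girvan_newman(net, backend=config.community_backend)
        modules = communities.filter_modules(moduleset, config.module_min_size)
    except Exception as exc:
        _fail("community_detection", exc)
    membership = pd.DataFrame(
        [(node, mid, len(moduleset.modules[mid])) for node, mid in
         sorted(moduleset.partition.items())],
        columns=["protein", "module", "module_size"],
    )
    membership.to_csv(outdir / "module_membership.tsv", sep="\t", index=False)
    report["communities"] = {
        "modularity": moduleset.modularity,
        "n_communities": len(moduleset.modules),
        "n_modules_ge_min_size": len(modules),
        "module_sizes": [len(m) for _, m in modules],
    }
    logger.info("stage community_detection: %d communities, %d of size >= %d",
                len(moduleset.modules), len(modules), config.module_min_size)

    # --- module reversal tests ---
    try:
        lfc_a = communities.replicate_fold_changes(log2_matrix, "O19_vs_O1")
        lfc_b = communities.replicate_fold_changes(log2_matrix, "O19_vs_O1CyA")
        reversal = communities.run_reversal_tests(
            moduleset, lfc_a, lfc_b,
            min_size=config.module_min_size, alpha=config.reversal_alpha,
        )
        reversal.to_csv(outdir / "module_reversal.tsv", sep="\t",
                        index=False, float_format="%.6g")
    except Exception as exc:
        _fail("module_reversal", exc)
    report["module_reversal"] = {
        "n_flagged": int(reversal["flag"].sum()) if len(reversal) else 0,
        "flagged_modules": [int(m) for m in reversal.loc[reversal["flag"], "module"]]
        if len(reversal) else [],
    }
    logger.info("stage module_reversal: %d flagged module(s)",
                report["module_reversal"]["n_flagged"])

    # --- module enrichment ---
    if collection is not None:
        try:
            mod_enrich = communities.module_enrichment(
                moduleset, collection, net_input.protein_ids,
                min_size=config.module_min_size, alpha=config.enrich_alpha,
            )
            mod_enrich.to_csv(outdir / "module_enrichment.tsv", sep="\t",
                              index=False, float_format="%.6g")
            report["module_enrichment"] = {
                "n_modules_with_hit": int((mod_enrich["top_set"] != "none").sum())
                if len(mod_enrich) else 0,
            }
        except Exception as exc:
            _fail("module_enrichment", exc)

    # --- knowledge comparison ---
    if knowledge_table is None and config.knowledge_edges_path:
        knowledge_table = pd.read_csv(config.knowledge_edges_path, sep="\t")
    if pathway_genes is None and config.pathway_genes_path:
        pathway_genes = [
            ln.strip() for ln in open(config.pathway_genes_path) if ln.strip()
        ]
    if knowledge_table is not None and pathway_genes:
        try:
            knet = knowledge.build_knowledge_network(
                knowledge_table, pathway_genes, config.knowledge_min_score
            )
            shared = knowledge.overlap_nodes(net, knet, id_map=id_map)
            report["knowledge_comparison"] = {
                "knowledge_nodes": len(knet.nodes),
                "knowledge_edges": knet.n_edges,
                "overlap_nodes": len(shared),
            }
            if net.n_nodes:
                hubs, hist, median_deg = knowledge.degree_ranking(net, top_n=20)
                hubs.to_csv(outdir / "coexpression_hubs.tsv", sep="\t", index=False)
                hist.rename("count").to_csv(outdir / "degree_histogram.tsv", sep="\t")
                report["knowledge_comparison"]["median_coexpression_degree"] = median_deg
                report["knowledge_comparison"]["top_hubs"] = hubs["node"].tolist()
        except Exception as exc:
            _fail("knowledge_comparison", exc)

    _write_json(report, outdir / "report.json")
    return report


def run_from_network(config: PipelineConfig, edge_list_path) -> dict:
    """Entry point starting at an existing co-expression edge list.

    Skips everything upstream of community detection: reads the edge list,
    detects and filters modules, and (when knowledge inputs are supplied)
    computes the node overlap and hub ranking.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": config.thresholds()}
    try:
        edges = read_edge_list(edge_list_path)
        if not edges:
            raise ValueError(f"no edges in {edge_list_path}")
        net = network.network_from_edges(edges, {"source": str(edge_list_path)})
    except Exception as exc:
        _fail("load_network", exc)
    report["coexpression_network"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
    try:
        moduleset = communities.girvan_newman(net, backend=config.community_backend)
        modules = communities.filter_modules(moduleset, config.module_min_size)
    except Exception as exc:
        _fail("community_detection", exc)
    report["communities"] = {
        "modularity": moduleset.modularity,
        "n_communities": len(moduleset.modules),
        "n_modules_ge_min_size": len(modules),
        "module_sizes": [len(m) for _, m in modules],
    }
    if config.knowledge_edges_path and config.pathway_genes_path:
        try:
            knowledge_table = pd.read_csv(config.knowledge_edges_path, sep="\t")
            pathway_genes = [
                ln.strip() for ln in open(config.pathway_genes_path) if ln.strip()
            ]
            knet = knowledge.build_knowledge_network(
                knowledge_table, pathway_genes, config.knowledge_min_score
            )
            id_map = dict(read_id_map(config.id_map_path)) if config.id_map_path else None
            shared = knowledge.overlap_nodes(net, knet, id_map=id_map)
            report["knowledge_comparison"] = {
                "knowledge_nodes": len(knet.nodes),
                "knowledge_edges": knet.n_edges,
                "overlap_nodes": len(shared),
            }
        except Exception as exc:
            _fail("knowledge_comparison", exc)
    _write_json(report, outdir / "report.json")
    return report
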