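"""End-to-end pipeline: RI annotation -> DEGs -> intersection -> weights ->
enrichment with re-ranking -> network exports, with a JSON run report.

Every threshold and scale decision actually applied is logged, because
boundary semantics (strict vs inclusive cuts, percent vs fraction content,
0-1 vs 0-1000 PPI scores) are exactly where published network-pharmacology
analyses become irreproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import chem_profile as cp
from . import enrichment as en
from . import gene_sets as gs
from . import network as nw
from . import weighting as wt
from .errors import StageError, ValidationError, WcnpError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and scale switches for one pipeline run."""

    components: str
    ladder: Optional[str] = None
    target_map: str = ""
    disease_genes: str = ""
    de_table: str = ""
    gmt: str = ""
    ppi: Optional[str] = None
    out_dir: str = "wcnp_out"
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    fdr_strict: bool = True
    lfc_inclusive: bool = True
    ppi_min_conf: float = 0.9
    k_min: int = 0
    content_scale: str = "percent"
    ppi_score_scale: str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0.0 < self.fdr_max <= 1.0):
            raise ValidationError("fdr_max must be in (0, 1]")
        if self.lfc_min < 0:
            raise ValidationError("lfc_min must be >= 0")
        if not (0.0 <= self.ppi_min_conf <= 1.0):
            raise ValidationError("ppi_min_conf must be in [0, 1]")
        if self.k_min < 0:
            raise ValidationError("k_min must be >= 0")
        for label, p in [("components", self.components),
                         ("target_map", self.target_map),
                         ("disease_genes", self.disease_genes),
                         ("de_table", self.de_table), ("gmt", self.gmt)]:
            if not p or not Path(p).exists():
                raise ValidationError(f"input {label!r} missing or not found: {p!r}")
        for label, p in [("ladder", self.ladder), ("ppi", self.ppi)]:
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input {label!r} not found: {p!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON).

    The first failing stage aborts with a stage-named error; outputs written
    before the failure are flagged as partial in the report file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
        "status": "partial",
    }
    report_path = out / "run_report.json"

    def _checkpoint():
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    def _stage(name):
        logger.info("stage %s starting", name)
        return name

    try:
        # --- chem profile / RI ------------------------------------------------
        stage = _stage("ri")
        table = cp.read_component_table(config.components, config.content_scale)
        logger.info("content scale: %s", config.content_scale)
        if config.ladder:
            ladder = cp.read_alkane_ladder(config.ladder)
            table = cp.annotate_table(table, ladder)
            annotated = out / "components_annotated.csv"
            cp.write_component_table(table, annotated)
            report["outputs"]["components_annotated"] = str(annotated)
        report["stages"]["ri"] = {
            "n_components": len(table),
            "total_area_pct": table.total_area_pct,
        }
        _checkpoint()

        # --- DEGs ------------------------------------------------------------
        stage = _stage("degs")
        de = gs.read_de_table(config.de_table)
        degs = gs.select_degs(
            de, config.fdr_max, config.lfc_min,
            fdr_strict=config.fdr_strict, lfc_inclusive=config.lfc_inclusive,
        )
        logger.info(
            "DEG thresholds applied: fdr %s %g, |log2fc| %s %g",
            "<" if config.fdr_strict else "<=", config.fdr_max,
            ">=" if config.lfc_inclusive else ">", config.lfc_min,
        )
        deg_path = out / "degs.txt"
        gs.write_gene_list(degs.selected, deg_path)
        report["outputs"]["degs"] = str(deg_path)
        report["stages"]["degs"] = {
            "n_selected": len(degs.selected),
            "n_up": degs.n_up,
            "n_down": degs.n_down,
        }
        _checkpoint()

        # --- intersection ------------------------------------------------------
        stage = _stage("intersect")
        edges = wt.read_target_map(config.target_map)
        disease = gs.read_gene_list(config.disease_genes, "disease")
        targets = gs.GeneSet("component_targets", edges.targets)
        key = gs.three_way_intersection(targets, disease, degs.selected)
        key_path = out / "key_targets.txt"
        gs.write_gene_list(key, key_path)
        report["outputs"]["key_targets"] = str(key_path)
        report["stages"]["intersect"] = {
            "n_component_targets": len(targets),
            "n_disease_genes": len(disease),
            "n_degs": len(degs.selected),
            "n_key_targets": len(key),
            "venn": gs.venn_counts(targets, disease, degs.selected),
        }
        _checkpoint()

        # --- weighting -----------------------------------------------------------
        stage = _stage("weigh")
        collection = en.read_gmt(config.gmt)
        weights = wt.compute_weights(table, edges, collection.as_gene_map())
        weight_paths = wt.write_weight_tables(weights, out / "weights")
        report["outputs"]["weights"] = {k: str(v) for k, v in weight_paths.items()}
        report["stages"]["weigh"] = {
            "n_components_scored": len(weights.a_scores),
            "n_targets_scored": len(weights.b_scores),
            "n_pathways_scored": len(weights.c_scores),
        }
        _checkpoint()

        # --- enrichment -------------------------------------------------------------
        stage = _stage("enrich")
        if len(key) == 0:
            logger.warning("key-target set is empty; enrichment skipped")
            report["stages"]["enrich"] = {"skipped": "empty key-target set"}
        else:
            result = en.hypergeom_enrich(key, collection, k_min=config.k_min)
            unweighted_path = out / "enrichment_unweighted.tsv"
            result.write(unweighted_path)
            reranked = en.rerank_by_weight(result, weights.c_scores)
            reranked_path = out / "enrichment_reranked.tsv"
            reranked.write(reranked_path)
            report["outputs"]["enrichment_unweighted"] = str(unweighted_path)
            report["outputs"]["enrichment_reranked"] = str(reranked_path)
            top = reranked.table.iloc[0]
            report["stages"]["enrich"] = {
                "n_pathways_tested": len(result),
                "top_weighted_pathway": str(top["pathway_id"]),
                "top_weighted_c": float(top["weight_c"]),
                "top_weighted_rank_delta": int(top["rank_delta"]),
            }
        _checkpoint()

        # --- network --------------------------------------------------------------
        stage = _stage("network")
        ppi_filtered = None
        if config.ppi:
            ppi_raw = nw.read_ppi(config.ppi, scale=config.ppi_score_scale)
            logger.info("PPI confidence filter: score > %g", config.ppi_min_conf)
            ppi_filtered = nw.filter_ppi_edges(ppi_raw, config.ppi_min_conf)
            ppi_path = out / "ppi_filtered.tsv"
            nw.write_ppi(ppi_filtered, ppi_path)
            report["outputs"]["ppi_filtered"] = str(ppi_path)
            report["stages"]["ppi"] = {
                "n_edges_in": len(ppi_raw),
                "n_edges_kept": len(ppi_filtered),
            }
        net = nw.build_tripartite(table, edges, collection, key, ppi=ppi_filtered)
        net = nw.drop_isolated_nodes(net)
        sif_path = out / "network.sif"
        graphml_path = out / "network.graphml"
        nw.write_sif(net, sif_path)
        nw.write_graphml(net, graphml_path)
        report["outputs"]["network_sif"] = str(sif_path)
        report["outputs"]["network_graphml"] = str(graphml_path)
        report["stages"]["network"] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "n_component_nodes": len(net.nodes_of_kind("component")),
            "n_target_nodes": len(net.nodes_of_kind("target")),
            "n_pathway_nodes": len(net.nodes_of_kind("pathway")),
        }
        report["status"] = "ok"
        _checkpoint()
    except WcnpError as exc:
        report["status"] = "failed"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _checkpoint()
        raise StageError(stage, str(exc)) from exc
    return report
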