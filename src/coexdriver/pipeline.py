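"""Configuration-driven orchestration of the full analysis.

Stages run in the method's order: differential expression → interaction-map
cleaning → centrality → regulator-allied subnetwork → per-condition
correlation maps → differential co-expression → semantic similarity →
driver genes → over-representation → GWAS overlap.  Every intermediate is
written as TSV under the run directory and a machine-readable manifest
records the count at each stage, so two runs with the same inputs and
configuration produce byte-identical manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import coexpr, diffexpr, prioritize, semsim, topology
from .io import (
    GenePanel,
    read_annotations,
    read_associations,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gmt,
    write_edge_list,
)

log = logging.getLogger("coexdriver")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for one pipeline run.

    Threshold defaults are the published operating point of the method:
    adjusted p <= 0.05 with |signed FC| >= 1.2 for differential expression,
    r >= 0.8 for co-expression, |Δr| >= 0.5 for differential co-expression,
    semantic score >= 0.5, top 25% betweenness for bottlenecks, mean + 2 SD
    degree for hubs, and p <= 0.01 / FDR < 0.05 for enrichment.
    """

    # input paths
    expression: str = ""
    conditions: str = ""
    edges: str = ""
    obo: str = ""
    annotations: str = ""
    seed_panel: str = ""
    nkpf_panel: str = ""
    gene_sets: str = ""       # optional GMT
    associations: str = ""    # optional GWAS-style TSV
    # thresholds
    p_max: float = 0.05
    fc_min: float = 1.2
    r_min: float = 0.8
    delta_min: float = 0.5
    sem_min: float = 0.5
    bottleneck_fraction: float = 0.25
    hub_sd_multiplier: float = 2.0
    enrich_p: float = 0.01
    enrich_fdr: float = 0.05
    gwas_p: float = 0.01
    # options
    t_test_variant: str = "welch"      # or "student"
    sd_variant: str = "sample"         # or "population"
    namespace: str = "molecular_function"
    path_bound: int = 2
    use_raw_p: bool = False
    restrict_ppim_to_degs: bool = True
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        checks = [
            (0 < self.p_max <= 1, "p_max must be in (0, 1]"),
            (self.fc_min >= 1, "fc_min must be >= 1"),
            (-1 <= self.r_min <= 1, "r_min must be in [-1, 1]"),
            (0 <= self.delta_min <= 2, "delta_min must be in [0, 2]"),
            (0 <= self.sem_min <= 1, "sem_min must be in [0, 1]"),
            (0 < self.bottleneck_fraction <= 1, "bottleneck_fraction must be in (0, 1]"),
            (self.hub_sd_multiplier >= 0, "hub_sd_multiplier must be >= 0"),
            (0 < self.enrich_p <= 1, "enrich_p must be in (0, 1]"),
            (0 < self.enrich_fdr <= 1, "enrich_fdr must be in (0, 1]"),
            (0 < self.gwas_p <= 1, "gwas_p must be in (0, 1]"),
            (self.t_test_variant in ("welch", "student"), "t_test_variant must be welch|student"),
            (self.sd_variant in ("sample", "population"), "sd_variant must be sample|population"),
            (self.path_bound >= 1, "path_bound must be >= 1"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        for name in ("expression", "conditions", "edges", "obo", "annotations",
                     "seed_panel", "nkpf_panel"):
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"required input path {name!r} is not set")
            if not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        for name in ("gene_sets", "associations"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with the stage name and original cause.
    """
    config.validate()
    out = Path(out_dir)
    tables = out / "tables"
    networks = out / "networks"
    for d in (out, tables, networks):
        d.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    manifest: dict = {"config": asdict(config)}
    try:
        _run_stages(config, tables, networks, manifest)
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    return wrap


def _run_stages(config: PipelineConfig, tables: Path, networks: Path, manifest: dict) -> None:
    # --- inputs -----------------------------------------------------------
    matrix = _stage("read_expression")(read_expression, config.expression, config.conditions)
    seeds = _stage("read_panels")(read_gene_list, config.seed_panel)
    family = _stage("read_panels")(read_gene_list, config.nkpf_panel)
    panel = GenePanel(
        name="regulators",
        members=set(seeds) | set(family),
        category_of={**{g: "seed" for g in seeds}, **{g: "nkpf" for g in family}},
    )
    manifest["genes_in"] = len(matrix.gene_ids)
    manifest["samples"] = {
        "control": len(matrix.samples_in("control")),
        "case": len(matrix.samples_in("case")),
    }
    manifest["panel"] = {"seed": len(panel.seeds), "nkpf": len(panel.nkpf)}

    # --- differential expression -----------------------------------------
    def de_stage():
        results = diffexpr.de_statistics(matrix, equal_var=config.t_test_variant == "student")
        results = diffexpr.attach_q_values(results)
        selection = diffexpr.select_degs(
            results, p_max=config.p_max, fc_min=config.fc_min, use_raw_p=config.use_raw_p
        )
        diffexpr.write_de_report(results, selection, tables / "differential_expression.tsv")
        return selection

    selection = _stage("differential_expression")(de_stage)
    manifest["degs"] = {
        "up": len(selection.up),
        "down": len(selection.down),
        "total": len(selection.selected),
    }

    # --- interaction map and centrality ----------------------------------
    def ppim_stage():
        graph = read_edge_list(config.edges)
        if config.restrict_ppim_to_degs:
            graph = graph.subgraph(selection.selected).copy()
        if graph.number_of_edges() == 0:
            raise ValueError("interaction map has no edges after DEG restriction")
        write_edge_list(graph, networks / "ppim_edges.tsv")
        return graph

    ppim = _stage("ppim")(ppim_stage)
    manifest["ppim"] = {
        "nodes": ppim.number_of_nodes(),
        "edges": ppim.number_of_edges(),
        "edge_node_ratio": round(topology.edge_node_ratio(ppim), 4),
    }

    def centrality_stage():
        hubs = topology.select_hubs(
            ppim, sd_mode=config.sd_variant, multiplier=config.hub_sd_multiplier
        )
        bottlenecks = topology.select_bottlenecks(ppim, fraction=config.bottleneck_fraction)
        topology.write_centrality_report(
            ppim, hubs, bottlenecks, panel, tables / "centrality.tsv"
        )
        return hubs, bottlenecks

    hubs, bottlenecks = _stage("centrality")(centrality_stage)
    manifest["hubs"] = len(hubs)
    manifest["bottlenecks"] = len(bottlenecks)

    def rapin_stage():
        result = topology.build_rapin(ppim, hubs, bottlenecks, panel)
        write_edge_list(result.subnetwork, networks / "rapin_edges.tsv")
        return result

    rapin = _stage("rapin")(rapin_stage)
    manifest["rapin"] = {
        "nodes": rapin.subnetwork.number_of_nodes(),
        "edges": rapin.subnetwork.number_of_edges(),
        "missing_panel_genes": sorted(rapin.missing_panel_genes),
    }

    # --- correlation maps and differential co-expression ------------------
    def correlation_stage():
        genes = sorted(set(rapin.subnetwork.nodes()) & set(matrix.gene_ids))
        maps = {}
        for cond in ("control", "case"):
            cmap = coexpr.correlation_map(matrix, cond, genes)
            coexpr.write_correlation_map(cmap, tables / f"correlation_{cond}.tsv")
            maps[cond] = cmap
        return genes, maps

    corr_genes, cmaps = _stage("correlation_maps")(correlation_stage)
    manifest["correlation"] = {
        "genes": len(corr_genes),
        "pairs": len(cmaps["control"].r_of),
        "degenerate_pairs": {
            c: len(m.degenerate_pairs) for c, m in cmaps.items()
        },
    }

    def delta_stage():
        out = {}
        for src, dst in (("control", "case"), ("case", "control")):
            coexpressed = coexpr.threshold_pairs(cmaps[src], r_min=config.r_min)
            records, missing = coexpr.cross_condition_delta(
                coexpressed, cmaps[src], cmaps[dst], delta_min=config.delta_min
            )
            panel_records, partners = coexpr.panel_neighborhood(records, panel.members)
            out[src] = {
                "coexpressed": coexpressed,
                "records": records,
                "missing": missing,
                "panel_records": panel_records,
                "partners": partners,
            }
        coexpr.write_diffcoex(
            out["control"]["records"] + out["case"]["records"],
            tables / "differential_coexpression.tsv",
        )
        return out

    delta = _stage("differential_coexpression")(delta_stage)
    for cond in ("control", "case"):
        manifest[f"pairs_{cond}"] = {
            "coexpressed": len(delta[cond]["coexpressed"]),
            "coexpressed_genes": len(coexpr.genes_of(delta[cond]["coexpressed"])),
            "delta_filtered": len(delta[cond]["records"]),
            "panel_neighborhood": len(delta[cond]["panel_records"]),
            "panel_partners": len(delta[cond]["partners"]),
        }

    # --- semantic similarity ----------------------------------------------
    def semsim_stage():
        dag = semsim.load_obo(config.obo)
        annotations = read_annotations(config.annotations)
        out = {}
        for cond in ("control", "case"):
            scored, skipped = semsim.score_pairs(
                delta[cond]["panel_records"], annotations, dag, namespace=config.namespace
            )
            kept = semsim.filter_semsim(scored, score_min=config.sem_min)
            out[cond] = {"kept": kept, "skipped": skipped}
        semsim.write_semsim(
            out["control"]["kept"] + out["case"]["kept"], tables / "semantic_similarity.tsv"
        )
        return out

    sem = _stage("semantic_similarity")(semsim_stage)
    for cond in ("control", "case"):
        manifest[f"semsim_{cond}"] = {
            "robust_pairs": len(sem[cond]["kept"]),
            "robust_genes": len(coexpr.genes_of([r.pair for r in sem[cond]["kept"]])),
            "skipped_unannotated": len(sem[cond]["skipped"]),
        }

    # --- driver genes -----------------------------------------------------
    def driver_stage():
        calls = prioritize.driver_genes(
            [r.pair for r in sem["control"]["kept"]],
            [r.pair for r in sem["case"]["kept"]],
            panel,
            max_path=config.path_bound,
        )
        prioritize.write_driver_report(calls, tables / "driver_genes.tsv")
        return calls

    drivers = _stage("driver_genes")(driver_stage)
    manifest["drivers"] = sorted(c.gene for c in drivers)

    # --- optional enrichment and GWAS overlap -----------------------------
    if config.gene_sets:
        def enrich_stage():
            sets = read_gmt(config.gene_sets)
            query = coexpr.genes_of([r.pair for r in sem["control"]["kept"]])
            if not query:
                return []
            results = prioritize.hypergeometric_enrichment(
                query,
                sets,
                universe=matrix.gene_ids,
                p_max=config.enrich_p,
                fdr_max=config.enrich_fdr,
            )
            prioritize.write_enrichment_report(results, tables / "enrichment.tsv")
            return results

        enriched = _stage("enrichment")(enrich_stage)
        manifest["enriched_sets"] = [r.set_name for r in enriched]

    if config.associations:
        def gwas_stage():
            assoc = read_associations(config.associations)
            overlap = prioritize.gwas_overlap(
                (c.gene for c in drivers), assoc, p_max=config.gwas_p
            )
            prioritize.write_gwas_report(overlap, tables / "gwas_overlap.tsv")
            return overlap

        overlap = _stage("gwas_overlap")(gwas_stage)
        manifest["gwas"] = {
            "hits": len(overlap.hits),
            "drivers_without_hits": list(overlap.drivers_without_hits),
        }
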