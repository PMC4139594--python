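"""End-to-end orchestration: simulate/load inputs, run every stage, report.

Stage order mirrors the discovery procedure: mouse spatial co-expression
network -> human spatial and temporal differential screens -> screen
intersection (the "core" human list) -> cross-species mapping against the
mouse module -> association-network extension of the mouse module ->
annotation-set enrichment of the core list.  Every stage writes its
artifacts to disk and contributes one structured log line with its
input/output counts, because each stage is a filter whose attrition is the
scientific narrative.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import netio, published, simulate
from .config import PipelineConfig
from .enrichment import EnrichmentContext, enrich
from .extension import extend_list
from .genesets import write_gene_sets, read_gene_sets
from .matrix import read_expression_matrix, write_expression_matrix
from .orthology import intersect_lists, map_orthologs
from .screen import contrast_for, pass_list, run_screen
from .spatial import build_vz_network, mask_for
from .symbols import (GeneList, HUMAN, MOUSE, OrthologTable,
                      read_ortholog_table, write_gene_list, write_ortholog_table)

log = logging.getLogger(__name__)

INPUT_FILES = {
    "mouse_matrix": "mouse_matrix.tsv",
    "mouse_samples": "mouse_samples.tsv",
    "human_spatial_matrix": "human_spatial_matrix.tsv",
    "human_spatial_samples": "human_spatial_samples.tsv",
    "human_temporal_matrix": "human_temporal_matrix.tsv",
    "human_temporal_samples": "human_temporal_samples.tsv",
    "annotations": "annotations.gmt",
    "orthologs": "orthologs.tsv",
    "ground_truth": "ground_truth.json",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def simulate_inputs(out_dir: str | Path, seed: int = 0, *,
                    n_genes_mouse: int = 2104, n_genes_human: int = 3000,
                    n_core_human_only: int = 400, sigma: float = 0.3,
                    recipes: tuple[str, ...] = ("all",)) -> dict:
    """Write a full set of simulated pipeline inputs to ``out_dir``.

    Recipes: mouse-atlas, human-spatial, human-temporal, networks,
    annotations, or all.  Returns a summary dict of what was written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wanted = set(recipes)
    if "all" in wanted:
        wanted = {"mouse-atlas", "human-spatial", "human-temporal", "networks", "annotations"}
    summary: dict = {"seed": seed, "written": []}
    truth_doc: dict = {}

    mouse_params = simulate.SimulationParams.mouse_atlas(n_genes=n_genes_mouse,
                                                         sigma=sigma, seed=seed)
    if "mouse-atlas" in wanted:
        matrix, truth = simulate.simulate_mouse_atlas(mouse_params)
        write_expression_matrix(matrix, out_dir / INPUT_FILES["mouse_matrix"],
                                out_dir / INPUT_FILES["mouse_samples"])
        write_ortholog_table(truth.ortholog_map, out_dir / INPUT_FILES["orthologs"])
        truth_doc["mouse_planted"] = truth.planted_genes.members
        summary["written"] += [INPUT_FILES["mouse_matrix"], INPUT_FILES["orthologs"]]

    design = None
    if wanted & {"human-spatial", "human-temporal"}:
        sp_mat, sp_truth, tm_mat, tm_truth, design = simulate.simulate_human_panels(
            n_genes=n_genes_human, seed=seed, sigma=sigma,
            n_core_human_only=n_core_human_only)
        if "human-spatial" in wanted:
            write_expression_matrix(sp_mat, out_dir / INPUT_FILES["human_spatial_matrix"],
                                    out_dir / INPUT_FILES["human_spatial_samples"])
            truth_doc["human_spatial_planted"] = sp_truth.planted_genes.members
            summary["written"].append(INPUT_FILES["human_spatial_matrix"])
        if "human-temporal" in wanted:
            write_expression_matrix(tm_mat, out_dir / INPUT_FILES["human_temporal_matrix"],
                                    out_dir / INPUT_FILES["human_temporal_samples"])
            truth_doc["human_temporal_planted"] = tm_truth.planted_genes.members
            summary["written"].append(INPUT_FILES["human_temporal_matrix"])
        truth_doc["human_core"] = design.core

    if "networks" in wanted:
        query = list(published.MOUSE_VZ_13)
        decoys = [f"Mbg{i:05d}" for i in range(150)]
        networks, associated = simulate.simulate_association_compendium(
            query + decoys, query, seed=seed)
        net_dir = out_dir / "networks"
        net_dir.mkdir(exist_ok=True)
        for name, graph in networks.items():
            netio.write_network(graph, net_dir / f"{name}.graphml")
        truth_doc["associated_tier"] = associated
        summary["written"].append("networks/")

    if "annotations" in wanted:
        universe = design.universe if design is not None else (
            [f"HVZ{i:04d}" for i in range(407)] + [f"HBG{i:05d}" for i in range(2600)])
        planted = design.core if design is not None else [f"HVZ{i:04d}" for i in range(407)]
        sets = simulate.simulate_annotations(universe, planted, seed=seed)
        write_gene_sets(sets, out_dir / INPUT_FILES["annotations"])
        truth_doc["enriched_sets"] = [n for n in sets if not n.startswith("Background")]
        summary["written"].append(INPUT_FILES["annotations"])

    (out_dir / INPUT_FILES["ground_truth"]).write_text(
        json.dumps(truth_doc, indent=2) + "\n", encoding="utf-8")
    return summary


@dataclass
class RunArtifacts:
    """In-memory handles to every stage output of one pipeline run."""

    mouse_network: object = None
    mouse_module: GeneList | None = None
    spatial_screen: pd.DataFrame | None = None
    temporal_screen: pd.DataFrame | None = None
    core_list: GeneList | None = None
    cross_species_core: GeneList | None = None
    extended: object = None
    enrichment: pd.DataFrame | None = None
    fallback_orthologs: int = 0


def run_all(config: PipelineConfig, input_dir: str | Path, out_dir: str | Path) -> dict:
    """Execute the full pipeline on the inputs in ``input_dir``.

    Writes every intermediate artifact plus ``report.json`` and
    ``report.txt`` under ``out_dir`` and returns the report dict.
    Deterministic given inputs and config.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    art = RunArtifacts()

    def _stage(name):
        log.info("stage %s ...", name)
        return name

    stage = _stage("mouse_vz_network")
    try:
        mouse = read_expression_matrix(input_dir / INPUT_FILES["mouse_matrix"],
                                       input_dir / INPUT_FILES["mouse_samples"])
        mask = mask_for(mouse, target_structures="VZ", target_ages="E15.5")
        network = build_vz_network(mouse, mask, config)
        art.mouse_network = network
        art.mouse_module = GeneList("mouse_vz_module", network.nodes, species=MOUSE,
                                    provenance="spatial co-expression network nodes")
        netio.write_network(network.graph, out_dir / "mouse_vz_network.graphml")
        edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in network.graph.edges(data=True)],
            columns=["gene_a", "gene_b", "r"])
        edges.to_csv(out_dir / "mouse_vz_network_edges.tsv", sep="\t", index=False)
        write_gene_list(art.mouse_module, out_dir / "mouse_vz_module.txt")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = _stage("human_screens")
    try:
        sp = read_expression_matrix(input_dir / INPUT_FILES["human_spatial_matrix"],
                                    input_dir / INPUT_FILES["human_spatial_samples"])
        contrast = contrast_for(sp, "vz_svz_vs_rest", target_structures=("VZ", "SVZ"))
        art.spatial_screen = run_screen(sp, contrast, config)
        _write_screen(art.spatial_screen, out_dir / "human_spatial_screen.tsv")

        tm = read_expression_matrix(input_dir / INPUT_FILES["human_temporal_matrix"],
                                    input_dir / INPUT_FILES["human_temporal_samples"])
        stages = list(tm.samples["age"].unique())
        contrast = contrast_for(tm, "early_vs_later", target_ages=stages[0])
        art.temporal_screen = run_screen(tm, contrast, config)
        _write_screen(art.temporal_screen, out_dir / "human_temporal_screen.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = _stage("cross_species")
    try:
        spatial_list = GeneList("human_spatial_pass", pass_list(art.spatial_screen),
                                species=HUMAN)
        temporal_list = GeneList("human_temporal_pass", pass_list(art.temporal_screen),
                                 species=HUMAN)
        art.core_list = intersect_lists(spatial_list, temporal_list, name="human_core")
        write_gene_list(art.core_list, out_dir / "human_core_list.txt")

        ortho_path = input_dir / INPUT_FILES["orthologs"]
        table = read_ortholog_table(ortho_path) if ortho_path.exists() else OrthologTable()
        if not ortho_path.exists():
            log.info("no ortholog table found; relying on case-restyle fallback")
        mapped = map_orthologs(art.mouse_module, table, "mouse_to_human")
        art.fallback_orthologs = getattr(mapped, "fallback_count", 0)
        art.cross_species_core = intersect_lists(mapped, art.core_list,
                                                 name="mouse_human_core")
        write_gene_list(art.cross_species_core, out_dir / "cross_species_core.txt")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = _stage("network_extension")
    try:
        net_dir = input_dir / "networks"
        networks = {p.stem: netio.read_network(p) for p in sorted(net_dir.glob("*.graphml"))}
        art.extended = extend_list(networks, art.mouse_module, config)
        netio.write_network(art.extended.graph, out_dir / "mouse_extended_network.graphml")
        write_gene_list(GeneList("mouse_extended", art.extended.nodes, species=MOUSE),
                        out_dir / "mouse_extended_list.txt")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = _stage("enrichment")
    try:
        sets = read_gene_sets(input_dir / INPUT_FILES["annotations"], species=HUMAN)
        context = EnrichmentContext(query=art.core_list, sets=sets)
        art.enrichment = enrich(context)
        art.enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    report = make_report(art, config, out_dir)
    return report


def _write_screen(table: pd.DataFrame, path: Path) -> None:
    out = table.rename(columns={"passed": "pass"})
    header = (f"# test: {table.attrs.get('test', 'welch')}\t"
              f"contrast: {table.attrs.get('contrast', '')}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False)


def make_report(art: RunArtifacts, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Aggregate stage outputs into report.json / report.txt (no recomputation)."""
    out_dir = Path(out_dir)
    report: dict = {
        "config": config.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "networkx": nx.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "stages": {},
    }
    if art.mouse_network is not None:
        report["stages"]["mouse_vz_network"] = {
            "n_prefiltered": len(art.mouse_network.prefiltered_genes),
            "n_nodes": len(art.mouse_network),
            "n_edges": art.mouse_network.graph.number_of_edges(),
            "members": art.mouse_module.members,
        }
    for key, table in (("human_spatial_screen", art.spatial_screen),
                       ("human_temporal_screen", art.temporal_screen)):
        if table is not None:
            report["stages"][key] = {
                "n_genes": int(len(table)),
                "family_size": int(table["family_size"].iloc[0]) if len(table) else 0,
                "n_passed": int(table["passed"].sum()),
            }
    if art.core_list is not None:
        report["stages"]["human_core"] = {"n_genes": len(art.core_list)}
    if art.cross_species_core is not None:
        report["stages"]["cross_species_core"] = {
            "n_genes": len(art.cross_species_core),
            "members": art.cross_species_core.members,
            "ortholog_fallbacks": art.fallback_orthologs,
        }
    if art.extended is not None:
        report["stages"]["mouse_extended_network"] = {
            "n_nodes": len(art.extended),
            "n_query": len(art.extended.query),
            "n_associated": len(art.extended.associated),
        }
    if art.enrichment is not None:
        top = art.enrichment.head(10)
        report["stages"]["enrichment"] = {
            "n_sets": int(len(art.enrichment)),
            "n_significant": int(art.enrichment["significant"].sum()),
            "top_rows": top.to_dict(orient="records"),
        }

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                                         encoding="utf-8")
    lines = ["pipeline run report", "==================", ""]
    for stage_name, info in report["stages"].items():
        lines.append(f"[{stage_name}]")
        for key, value in info.items():
            if key in ("members", "top_rows"):
                continue
            lines.append(f"  {key}: {value}")
        lines.append("")
    (out_dir / "report.txt").write_text("\n".join(lines), encoding="utf-8")
    return report
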