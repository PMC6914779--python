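"""End-to-end orchestration: normalize → screen → network → cluster → select.

``run_pipeline`` executes every stage on either user-supplied files or a
synthetic cohort, writes each stage's outputs as plain-text tables under
the output directory, and returns a manifest recording settings, the
counts at every filter (analytes tested, modulated, seeds mapped, model
nodes/edges, clusters retained, signature size) and SHA-256 hashes of all
written files.  The pipeline is a pure function of (inputs, config,
seed): identical configurations produce hash-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .clusters import enrich_clusters, infomap_cluster
from .containers import SimGroundTruth
from .diff import ALPHA, LFC, cohort_summary, differential_table, select_modulated
from .network import betweenness, build_network, centrality_table, map_seed_nodes
from .normalize import QC_WINDOW, normalize_pipeline
from .report import heatmap_matrix
from .select import FREQUENCY_THRESHOLD, prepare_design, run_selection
from .simulate import GraphSimConfig, SimConfig, simulate_cohort, simulate_knowledge_graph


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for a pipeline run.

    Leave the input paths at ``None`` to run on a synthetic cohort and
    knowledge graph generated from ``sim`` / ``graph_sim`` (their seeds
    are derived from ``seed``).
    """

    outdir: Path = Path("results/pipeline")
    seed: int = 0
    # input paths (all-or-none per data kind)
    rfu_values: Path | None = None
    rfu_analytes: Path | None = None
    samples: Path | None = None
    edge_list: Path | None = None
    gmt: Path | None = None
    mapping: Path | None = None
    # synthetic fallbacks
    sim: SimConfig = field(default_factory=SimConfig)
    graph_sim: GraphSimConfig = field(default_factory=GraphSimConfig)
    # thresholds
    alpha: float = ALPHA
    lfc: float = LFC
    qc_window: tuple = QC_WINDOW
    frequency_threshold: float = FREQUENCY_THRESHOLD
    pathway_size_window: tuple = (10, 500)
    # stage toggles
    run_network: bool = True
    run_select: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t")
        written.append(path)

    manifest: dict = {
        "seed": config.seed,
        "settings": {
            "alpha": config.alpha,
            "lfc": config.lfc,
            "qc_window": list(config.qc_window),
            "frequency_threshold": config.frequency_threshold,
            "pathway_size_window": list(config.pathway_size_window),
        },
        "counts": {},
        "stages": [],
    }

    # -- stage: inputs ------------------------------------------------------
    if config.rfu_values is not None:
        raw = io.read_rfu(config.rfu_values, config.rfu_analytes)
        samples = io.read_samples(config.samples)
        truth = SimGroundTruth()
    else:
        sim = SimConfig(**{**config.sim.__dict__, "seed": config.seed})
        raw, samples, truth = simulate_cohort(sim)
    manifest["stages"].append("inputs")
    manifest["counts"]["n_samples"] = int(raw.values.shape[0])
    manifest["counts"]["n_analytes"] = int(len(raw.assay_analytes))

    # -- stage: normalization ----------------------------------------------
    normalized, sfs = normalize_pipeline(raw, window=config.qc_window)
    emit(sfs.report(), "scale_factors.tsv")
    samples = samples.loc[samples.index.intersection(normalized.samples)]
    manifest["stages"].append("normalize")
    manifest["counts"]["n_qc_excluded"] = int(
        (sfs.qc_status["status"] == "excluded").sum()
    )

    emit(cohort_summary(samples), "cohort_summary.tsv")

    # -- stage: differential screen ----------------------------------------
    results = differential_table(
        normalized, samples, alpha=config.alpha, lfc=config.lfc
    )
    emit(results, "differential.tsv")
    modulated = select_modulated(results, alpha=config.alpha, lfc=config.lfc)
    manifest["stages"].append("diff")
    manifest["counts"]["n_tested"] = int(results.shape[0])
    manifest["counts"]["n_modulated"] = len(modulated)

    if not modulated:
        manifest["message"] = "no modulated analytes: downstream stages skipped"
        manifest["counts"]["signature_size"] = 0
        manifest["signature"] = []
        _finish(manifest, written, out)
        return manifest

    # -- stage: network model ----------------------------------------------
    if config.run_network:
        if config.edge_list is not None:
            graph = io.read_edge_list(config.edge_list)
            pathways = io.read_gmt(config.gmt) if config.gmt else {}
            mapping = io.read_mapping(config.mapping) if config.mapping else {}
        else:
            graph, pathways, gtruth = simulate_knowledge_graph(
                GraphSimConfig(**{**config.graph_sim.__dict__, "seed": config.seed + 1}),
                analyte_ids=list(raw.assay_analytes),
            )
            mapping = gtruth.analyte_map
            truth.planted_communities = gtruth.planted_communities
            truth.planted_pathways = gtruth.planted_pathways
            truth.analyte_map = gtruth.analyte_map

        seed_map = map_seed_nodes(modulated, graph, mapping)
        manifest["counts"]["n_seed_nodes"] = len(seed_map.seeds)
        manifest["counts"]["n_unmapped_analytes"] = len(seed_map.unmapped)

        model = build_network(graph, seed_map.seeds)
        if model.graph.number_of_nodes() > 0:
            betweenness(model)
        manifest["counts"]["n_model_nodes"] = model.graph.number_of_nodes()
        manifest["counts"]["n_model_edges"] = model.graph.number_of_edges()
        manifest["stages"].append("network")

        if model.graph.number_of_nodes() > 0:
            # seed log2fc annotation (mean over analytes mapping to the node)
            node_lfc: dict = {}
            for analyte, nodes in seed_map.analyte_to_nodes.items():
                for nd in nodes:
                    node_lfc.setdefault(nd, []).append(results.loc[analyte, "log2fc"])
            assignment = infomap_cluster(model, seed=config.seed + 2)
            for n in model.graph.nodes:
                model.graph.nodes[n]["seed"] = bool(n in model.seeds)
                model.graph.nodes[n]["betweenness"] = float(model.betweenness[n])
                model.graph.nodes[n]["cluster"] = int(assignment.membership[n])
                if n in node_lfc:
                    model.graph.nodes[n]["log2fc"] = float(np.mean(node_lfc[n]))
            gml = out / "network_model.graphml"
            io.write_graphml(model.graph, gml)
            written.append(gml)
            emit(centrality_table(model), "centrality.tsv")

            emit(assignment.table, "clusters.tsv")
            emit(
                pd.Series(assignment.membership, name="cluster").rename_axis("node").to_frame(),
                "node_clusters.tsv",
            )
            manifest["counts"]["n_clusters"] = int(assignment.table.shape[0])
            manifest["counts"]["n_clusters_retained"] = len(assignment.retained)
            manifest["stages"].append("cluster")

            universe = set().union(*pathways.values()) if pathways else set()
            if universe:
                enrichment = enrich_clusters(
                    assignment, pathways, universe,
                    size_window=config.pathway_size_window,
                )
                emit(enrichment.set_index(["cluster", "pathway"]), "enrichment.tsv")
                manifest["counts"]["n_enrichment_tests"] = int(enrichment.shape[0])

    # -- stage: signature selection ----------------------------------------
    if config.run_select:
        design = prepare_design(normalized, modulated, samples)
        selection = run_selection(design, threshold=config.frequency_threshold)
        emit(selection.report(), "selection.tsv")
        io.write_json(
            {
                "lambda_ridge": selection.lambda_ridge,
                "lambda_alasso": selection.lambda_alasso,
                "n_jackknife": selection.n_jackknife,
                "n_failed": selection.n_failed,
                "frequency_threshold": config.frequency_threshold,
            },
            out / "selection_params.json",
        )
        written.append(out / "selection_params.json")
        manifest["counts"]["signature_size"] = len(selection.signature)
        manifest["signature"] = sorted(selection.signature)
        manifest["stages"].append("select")

        hm = heatmap_matrix(normalized, selection.signature, samples)
        if hm is not None:
            emit(hm[0], "heatmap_z.tsv")

    if truth.signal_analytes:
        io.write_ground_truth(truth, out / "ground_truth.json")
        written.append(out / "ground_truth.json")

    _finish(manifest, written, out)
    return manifest


def _finish(manifest: dict, written: list, out: Path) -> None:
    manifest["files"] = {p.name: _sha256(p) for p in sorted(written)}
    io.write_json(manifest, out / "manifest.json")
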