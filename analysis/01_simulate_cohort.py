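#!/usr/bin/env python
"""Generate the demonstration inputs: a synthetic heart-failure cohort and
knowledge graph with known ground truth.

Emulated study conditions: 84 cases (cardiovascular death within 3 years)
matched with 84 controls, 1310 plasma analytes on an aptamer array with 12
hybridization controls, per-sample multiplicative biases, 25 analytes with
a planted +1 log2 group shift, and a planted-community molecular graph
with pathway sets.  Everything downstream (02-07) reads these files.
"""

from pathlib import Path

from somanet import GraphSimConfig, SimConfig, io, simulate_cohort, simulate_knowledge_graph

OUT = Path("results/demo/inputs")
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort_cfg = SimConfig(seed=SEED)
    matrix, samples, truth = simulate_cohort(cohort_cfg)
    io.write_rfu(matrix, OUT / "rfu.tsv", OUT / "analytes.tsv")
    io.write_samples(samples, OUT / "samples.tsv")

    graph, pathways, gtruth = simulate_knowledge_graph(
        GraphSimConfig(seed=SEED + 1), analyte_ids=list(matrix.assay_analytes)
    )
    io.write_edge_list(graph, OUT / "edges.tsv")
    io.write_graphml(graph, OUT / "knowledge_graph.graphml")
    io.write_gmt(pathways, OUT / "pathways.gmt")
    io.write_mapping(gtruth.analyte_map, OUT / "mapping.tsv")

    truth.planted_communities = gtruth.planted_communities
    truth.planted_pathways = gtruth.planted_pathways
    truth.analyte_map = gtruth.analyte_map
    io.write_ground_truth(truth, OUT / "ground_truth.json")

    print(f"cohort: {matrix.values.shape[0]} samples x {len(matrix.assay_analytes)} analytes "
          f"(+{len(matrix.hyb_controls)} hybridization controls)")
    print(f"planted signals: {len(truth.signal_analytes)} analytes at "
          f"log2FC = {cohort_cfg.effect_log2fc}")
    print(f"knowledge graph: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges, {len(pathways)} pathway sets")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
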