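#!/usr/bin/env python
"""Build the seed-node molecular network and rank nodes by centrality.

Modulated analytes are mapped to graph nodes (seed nodes); the model keeps
connectors adjacent to >= 2 seeds, seeds with a qualifying interaction,
and seed-seed / seed-connector edges only.  Nodes are ranked by normalized
betweenness centrality.
"""

from pathlib import Path

import pandas as pd

from somanet import (
    betweenness, build_network, centrality_table, io, map_seed_nodes,
    select_modulated, top_central,
)

IN = Path("results/demo/inputs")
DIFF = Path("results/demo/differential")
OUT = Path("results/demo/network")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(DIFF / "differential.tsv", sep="\t", index_col=0)
    modulated = select_modulated(table)
    graph = io.read_edge_list(IN / "edges.tsv")
    mapping = io.read_mapping(IN / "mapping.tsv")

    seed_map = map_seed_nodes(modulated, graph, mapping)
    print(f"{len(modulated)} modulated analytes mapped to "
          f"{len(seed_map.seeds)} seed nodes "
          f"({len(seed_map.unmapped)} unmapped)")

    model = build_network(graph, seed_map.seeds)
    betweenness(model)
    print(f"network model: {model.graph.number_of_nodes()} nodes "
          f"({len(model.seeds)} seeds, {len(model.connectors)} connectors), "
          f"{model.graph.number_of_edges()} edges")

    io.write_graphml(model.graph, OUT / "network_model.graphml")
    centrality_table(model).to_csv(OUT / "centrality.tsv", sep="\t")
    print("top 10 nodes by betweenness centrality:")
    for node in top_central(model, 10):
        print(f"  {node}: {model.betweenness[node]:.4f}")


if __name__ == "__main__":
    main()
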