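"""Seed-node molecular network construction and betweenness ranking.

Significantly modulated analytes are mapped onto knowledge-graph nodes
("seed nodes"; one analyte may map to several nodes).  The network model
is the subgraph defined by three inclusion criteria:

1. every non-seed node that is a direct neighbour of at least two seed
   nodes (a *connector*);
2. every seed node with at least one interaction with another seed node
   or with a connector;
3. the edges joining two seed nodes, or a seed node and a connector —
   connector–connector edges are *not* included.

By construction no node of the model is isolated and every connector has
at least two seed neighbours inside the model.  Nodes are then ranked by
betweenness centrality: the fraction of all-pairs shortest paths passing
through a node, normalized by the (N−1)(N−2)/2 unordered pairs, so values
lie in [0, 1].  Disconnected pairs contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class SeedMapping:
    """Analyte -> node mapping outcome."""

    seeds: set
    analyte_to_nodes: dict
    unmapped: list


@dataclass
class NetworkModel:
    """Constructed subgraph with seed flags and node annotations."""

    graph: nx.Graph
    seeds: set
    log2fc: dict = field(default_factory=dict)  # seed node -> log2fc annotation
    betweenness: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)  # node -> cluster id

    @property
    def connectors(self) -> set:
        return set(self.graph.nodes) - self.seeds

    def validate(self) -> None:
        for v in self.connectors:
            seed_nbrs = sum(1 for u in self.graph.neighbors(v) if u in self.seeds)
            if seed_nbrs < 2:
                raise AssertionError(f"connector {v!r} has {seed_nbrs} seed neighbours")


def make_knowledge_graph(edges, node_types=None) -> nx.Graph:
    """Build a simple undirected graph from (u, v[, source]) records.

    Duplicate edges (e.g. the same interaction reported by several source
    databases) are collapsed to one edge with concatenated source tags;
    self-loops are dropped.
    """
    g = nx.Graph()
    for rec in edges:
        u, v = rec[0], rec[1]
        src = rec[2] if len(rec) > 2 else ""
        if u == v:
            continue
        if g.has_edge(u, v):
            old = g[u][v].get("sources", "")
            if src and src not in old.split(";"):
                g[u][v]["sources"] = f"{old};{src}" if old else src
        else:
            g.add_edge(u, v, sources=src)
    if node_types:
        nx.set_node_attributes(g, node_types, "node_type")
    return g


def map_seed_nodes(modulated, graph: nx.Graph, mapping: dict) -> SeedMapping:
    """Map modulated analytes onto graph nodes.

    ``mapping`` is analyte -> iterable of node ids (one-to-many allowed).
    Analytes without an entry are recorded as unmapped, not fatal; a mapped
    node id absent from the graph is an error.
    """
    seeds, unmapped, a2n = set(), [], {}
    for analyte in modulated:
        nodes = list(mapping.get(analyte, []))
        if not nodes:
            unmapped.append(analyte)
            continue
        for n in nodes:
            if n not in graph:
                raise ValueError(f"mapped node {n!r} absent from the knowledge graph")
        a2n[analyte] = nodes
        seeds.update(nodes)
    return SeedMapping(seeds=seeds, analyte_to_nodes=a2n, unmapped=unmapped)


def build_network(graph: nx.Graph, seeds) -> NetworkModel:
    """Apply the three inclusion criteria to extract the network model."""
    seeds = set(seeds)
    missing = seeds - set(graph.nodes)
    if missing:
        raise ValueError(f"seed nodes absent from the graph: {sorted(missing)[:5]}")

    connectors = set()
    for v in graph.nodes:
        if v in seeds:
            continue
        if sum(1 for u in graph.neighbors(v) if u in seeds) >= 2:
            connectors.add(v)

    kept_seeds = set()
    for s in seeds:
        for u in graph.neighbors(s):
            if u in seeds or u in connectors:
                kept_seeds.add(s)
                break

    model = nx.Graph()
    model.add_nodes_from(
        (n, dict(graph.nodes[n], seed=(n in seeds))) for n in kept_seeds | connectors
    )
    for u, v, data in graph.edges(data=True):
        u_seed, v_seed = u in seeds, v in seeds
        if (u_seed and v_seed) or (u_seed and v in connectors) or (v_seed and u in connectors):
            model.add_edge(u, v, **data)

    out = NetworkModel(graph=model, seeds=kept_seeds)
    out.validate()
    return out


def betweenness(model: NetworkModel) -> dict:
    """Normalized betweenness centrality for every node of the model.

    Values are stored on the model and returned.  Graphs with fewer than
    three nodes get all-zero centralities by convention.
    """
    g = model.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network model")
    if g.number_of_nodes() < 3:
        model.betweenness = {n: 0.0 for n in g.nodes}
    else:
        model.betweenness = nx.betweenness_centrality(g, normalized=True)
    return model.betweenness


def top_central(model: NetworkModel, k: int) -> list:
    """Top-k nodes by descending centrality; ties broken by node id."""
    if not model.betweenness:
        betweenness(model)
    ranked = sorted(model.betweenness.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [n for n, _ in ranked[: max(k, 0)]]


def centrality_table(model: NetworkModel) -> pd.DataFrame:
    """Ranking table (node, type, seed flag, betweenness) sorted as top_central."""
    if not model.betweenness:
        betweenness(model)
    order = top_central(model, model.graph.number_of_nodes())
    return pd.DataFrame(
        {
            "node": order,
            "node_type": [model.graph.nodes[n].get("node_type", "") for n in order],
            "seed": [n in model.seeds for n in order],
            "betweenness": [model.betweenness[n] for n in order],
        }
    ).set_index("node")
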