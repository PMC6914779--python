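"""Map-equation clustering of the network model and pathway annotation.

Nodes are partitioned with the InfoMap algorithm (two-level map equation,
undirected, unweighted; igraph implementation).  Clusters smaller than 5
nodes, or with one or fewer internal edges per node (internal edge count /
cluster size <= 1), are excluded from annotation.  Retained clusters are
annotated by overrepresentation against pathway node sets using the
one-sided hypergeometric (Fisher) tail, with pathways of fewer than 10 or
more than 500 members dropped beforehand, and Benjamini-Hochberg
adjustment within each cluster.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .diff import bh_adjust
from .network import NetworkModel

MIN_CLUSTER_SIZE = 5
PATHWAY_SIZE_WINDOW = (10, 500)


@dataclass
class ClusterAssignment:
    """Node partition plus per-cluster bookkeeping."""

    membership: dict  # node -> cluster id (1-based, by decreasing size)
    table: pd.DataFrame  # cluster × (size, internal_edges, retained, reason)

    def nodes_of(self, cluster_id) -> set:
        return {n for n, c in self.membership.items() if c == cluster_id}

    @property
    def retained(self) -> list:
        return list(self.table.index[self.table["retained"]])


def _internal_edges(graph, membership) -> dict:
    counts = {c: 0 for c in set(membership.values())}
    for u, v in graph.edges():
        if membership[u] == membership[v]:
            counts[membership[u]] += 1
    return counts


def infomap_cluster(model: NetworkModel, seed: int = 0, trials: int = 10) -> ClusterAssignment:
    """Two-level InfoMap partition of the model, deterministic given ``seed``."""
    g = model.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network model")
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    igg = ig.Graph(n=len(nodes), edges=edges, directed=False)

    state = random.getstate()
    try:
        random.seed(int(seed) & 0x7FFFFFFF)  # igraph draws from Python's random
        part = igg.community_infomap(trials=trials)
    finally:
        random.setstate(state)

    raw = {nodes[i]: part.membership[i] for i in range(len(nodes))}
    # relabel 1..K by decreasing size, ties by smallest member id, for stable output
    sizes = pd.Series(list(raw.values())).value_counts()
    order = sorted(
        sizes.index, key=lambda c: (-sizes[c], min(str(n) for n in nodes if raw[n] == c))
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    membership = {n: relabel[c] for n, c in raw.items()}
    model.clusters = membership

    internal = _internal_edges(g, membership)
    table = pd.DataFrame(
        {
            "size": pd.Series(list(membership.values())).value_counts().sort_index(),
            "internal_edges": pd.Series(internal).sort_index(),
        }
    ).sort_index()
    table.index.name = "cluster"
    assignment = ClusterAssignment(membership=membership, table=table)
    return filter_clusters(assignment)


def filter_clusters(assignment: ClusterAssignment) -> ClusterAssignment:
    """Apply the size and internal-edge-density exclusion rules.

    Retained ⇔ size >= 5 and internal_edges / size > 1.
    """
    table = assignment.table.copy()
    retained, reason = [], []
    for c, row in table.iterrows():
        size, edges = int(row["size"]), int(row["internal_edges"])
        why = []
        if size < MIN_CLUSTER_SIZE:
            why.append(f"size {size} < {MIN_CLUSTER_SIZE}")
        if edges / size <= 1:
            why.append(f"{edges}/{size} internal edges per node <= 1")
        retained.append(not why)
        reason.append("; ".join(why))
    table["retained"] = retained
    table["reason"] = reason
    return ClusterAssignment(membership=assignment.membership, table=table)


def fisher_enrichment_p(overlap: int, universe: int, pathway: int, cluster: int) -> float:
    """One-sided hypergeometric tail P(X >= overlap)."""
    if overlap > min(pathway, cluster):
        raise ValueError("overlap exceeds pathway or cluster size")
    return float(stats.hypergeom.sf(overlap - 1, universe, pathway, cluster))


def enrich_clusters(
    assignment: ClusterAssignment,
    pathways: dict,
    universe,
    size_window=PATHWAY_SIZE_WINDOW,
) -> pd.DataFrame:
    """Fisher overrepresentation of retained clusters against pathway sets.

    ``universe`` is the background node set (all annotated nodes); both
    pathways and clusters are intersected with it.  Pathways whose
    in-universe size falls outside ``size_window`` (inclusive) are dropped
    before testing.  Returns a (cluster, pathway) table with overlap, raw
    and per-cluster BH-adjusted p, and a best-pathway flag.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty annotation universe")
    lo, hi = size_window
    tested = {
        name: set(members) & universe
        for name, members in pathways.items()
    }
    tested = {k: v for k, v in tested.items() if lo <= len(v) <= hi}

    rows = []
    for c in assignment.retained:
        cluster_nodes = assignment.nodes_of(c) & universe
        if not cluster_nodes:
            continue
        ps = []
        for name in sorted(tested):
            pw = tested[name]
            overlap = len(cluster_nodes & pw)
            p = fisher_enrichment_p(overlap, len(universe), len(pw), len(cluster_nodes))
            ps.append((name, overlap, len(pw), p))
        if not ps:
            continue
        p_adj = bh_adjust([p for _, _, _, p in ps])
        best = min(range(len(ps)), key=lambda i: (p_adj[i], ps[i][0]))
        for i, (name, overlap, size, p) in enumerate(ps):
            rows.append(
                {
                    "cluster": c,
                    "pathway": name,
                    "pathway_size": size,
                    "overlap": overlap,
                    "p": p,
                    "p_adj": p_adj[i],
                    "best": i == best,
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster", "pathway", "pathway_size", "overlap", "p", "p_adj", "best"]
    )


def adjusted_rand_index(membership: dict, truth: dict) -> float:
    """ARI between a partition and the planted one, over shared nodes."""
    from sklearn.metrics import adjusted_rand_score

    nodes = sorted(set(membership) & set(truth), key=str)
    if not nodes:
        raise ValueError("no shared nodes between partitions")
    a = [membership[n] for n in nodes]
    b = [truth[n] for n in nodes]
    return float(adjusted_rand_score(b, a))
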