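"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles (enumeration,
dynamic programming, exhaustive summation, naive set logic) without
touching the implementation path it checks.
"""

from __future__ import annotations

import math
from collections import deque


def wilcoxon_exact_two_sided(case, control) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of the U null.

    The null distribution of U is built by dynamic programming over rank
    subsets (equivalent to enumerating all C(n1+n2, n1) assignments of the
    tie-free pooled ranks).  p = 2 * P(U >= max(u, n1*n2 - u)), capped at 1.
    """
    n1, n2 = len(case), len(control)
    pooled = sorted(list(case) + list(control))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w = sum(ranks[v] for v in case)
    u = w - n1 * (n1 + 1) // 2

    # ways[k][s] = number of k-subsets of ranks 1..N with rank sum s
    N = n1 + n2
    smax = N * (N + 1) // 2
    ways = [[0] * (smax + 1) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            row, prev = ways[k], ways[k - 1]
            for s in range(smax, r - 1, -1):
                row[s] += prev[s - r]
    total = math.comb(N, n1)
    offset = n1 * (n1 + 1) // 2
    u_hi = max(u, n1 * n2 - u)
    count = sum(
        ways[n1][s] for s in range(smax + 1) if (s - offset) >= u_hi
    )
    return min(1.0, 2.0 * count / total)


def betweenness_brute(graph) -> dict:
    """Normalized betweenness by per-pair BFS shortest-path counting.

    For every unordered pair (s, t), shortest-path counts sigma_st and
    through-v counts sigma_st(v) come from two independent BFS sweeps:
    v lies on a shortest s-t path iff d(s,v) + d(v,t) = d(s,t), in which
    case sigma_st(v) = sigma_sv * sigma_vt.  Normalization divides by
    (N-1)(N-2)/2; disconnected pairs contribute nothing.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    if n < 3:
        return score

    def bfs(source):
        dist = {source: 0}
        count = {source: 1}
        q = deque([source])
        while q:
            u = q.popleft()
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    count[v] = 0
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    count[v] += count[u]
        return dist, count

    sweeps = {v: bfs(v) for v in nodes}
    for i in range(n):
        s = nodes[i]
        dist_s, cnt_s = sweeps[s]
        for j in range(i + 1, n):
            t = nodes[j]
            if t not in dist_s:
                continue
            dist_t, cnt_t = sweeps[t]
            d = dist_s[t]
            sigma = cnt_s[t]
            for v in nodes:
                if v is s or v is t or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d:
                    score[v] += cnt_s[v] * cnt_t[v] / sigma
    norm = (n - 1) * (n - 2) / 2.0
    return {v: score[v] / norm for v in nodes}


def build_network_brute(graph, seeds):
    """Naive application of the three seed-network inclusion criteria.

    Returns (node set, edge set with frozenset edges).
    """
    seeds = set(seeds)
    connectors = {
        v
        for v in graph.nodes
        if v not in seeds and len(set(graph.neighbors(v)) & seeds) >= 2
    }
    kept_seeds = {
        s
        for s in seeds
        if set(graph.neighbors(s)) & (seeds | connectors)
    }
    edges = set()
    for u, v in graph.edges():
        if (u in seeds and v in seeds) or \
           (u in seeds and v in connectors) or (v in seeds and u in connectors):
            edges.add(frozenset((u, v)))
    return kept_seeds | connectors, edges


def hypergeom_tail_brute(overlap, universe, pathway, cluster) -> float:
    """P(X >= overlap) by exhaustive summation of hypergeometric terms."""
    total = 0.0
    denom = math.comb(universe, cluster)
    for k in range(overlap, min(pathway, cluster) + 1):
        if universe - pathway >= cluster - k:
            total += math.comb(pathway, k) * math.comb(universe - pathway, cluster - k) / denom
    return total


def bh_adjust_brute(p_values):
    """Direct step-up formula: p_adj(i) = min_{j >= i} m * p_(j) / j, capped."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adj[i] = min(1.0, running)
    return adj
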