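"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, closed-form
combinatorics) that never share code with the package paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

import networkx as nx


def enumerate_simple_paths(graph: nx.Graph, source, target):
    """All simple paths source→target by explicit DFS (no networkx helper)."""
    paths = []

    def extend(path):
        last = path[-1]
        if last == target:
            paths.append(list(path))
            return
        for nxt in graph.neighbors(last):
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([source])
    return paths


def weighted_distance(graph: nx.Graph, source, target, weight="weight"):
    """Min total edge weight over exhaustively enumerated simple paths."""
    best = inf
    for path in enumerate_simple_paths(graph, source, target):
        total = sum(
            graph.edges[u, v][weight] for u, v in zip(path, path[1:])
        )
        best = min(best, total)
    return best


def netshort_oracle(graph: nx.Graph, seeds: set) -> dict:
    """Seed-proximity scores recomputed from the definition by enumeration."""
    weighted = nx.Graph()
    weighted.add_nodes_from(graph.nodes)
    for u, v in graph.edges:
        bonus = (1 if u in seeds else 0) + (1 if v in seeds else 0)
        weighted.add_edge(u, v, weight=1.0 / (1.0 + bonus))
    raw = {}
    for node in graph.nodes:
        total = 0.0
        for seed in seeds:
            if seed == node:
                continue
            dist = weighted_distance(weighted, node, seed)
            if dist < inf:
                total += 1.0 / dist
        raw[node] = total
    peak = max(raw.values())
    for seed in seeds:
        raw[seed] = peak
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {v: 0.5 for v in raw}
    return {v: (x - lo) / (hi - lo) for v, x in raw.items()}


def _bfs_distances(graph: nx.Graph, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for nbr in graph.neighbors(node):
                if nbr not in dist:
                    dist[nbr] = dist[node] + 1
                    nxt.append(nbr)
        frontier = nxt
    return dist


def shortest_path_counts(graph: nx.Graph, source) -> tuple[dict, dict]:
    """(distances, number of shortest paths) from source, by layer DP."""
    dist = _bfs_distances(graph, source)
    counts = {source: 1}
    for node in sorted(dist, key=dist.get):
        if node == source:
            continue
        counts[node] = sum(
            counts[nbr]
            for nbr in graph.neighbors(node)
            if nbr in dist and dist[nbr] == dist[node] - 1
        )
    return dist, counts


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Normalized betweenness from pairwise shortest-path count ratios."""
    nodes = list(graph.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    dist_from = {}
    count_from = {}
    for v in nodes:
        dist_from[v], count_from[v] = shortest_path_counts(graph, v)
    for s, t in combinations(nodes, 2):
        if t not in dist_from[s]:
            continue
        d_st = dist_from[s][t]
        sigma_st = count_from[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist_from[s] or t not in dist_from[v]:
                continue
            if dist_from[s][v] + dist_from[v][t] == d_st:
                sigma_through = count_from[s][v] * count_from[v][t]
                score[v] += sigma_through / sigma_st
    if n > 2:
        norm = 2.0 / ((n - 1) * (n - 2))
        score = {v: x * norm for v, x in score.items()}
    return score


def degree_centrality_oracle(graph: nx.Graph) -> dict:
    n = graph.number_of_nodes()
    return {v: graph.degree(v) / (n - 1) for v in graph.nodes}


def linkers_oracle(graph: nx.Graph, selected: set) -> set:
    return {
        v
        for v in graph.nodes
        if v not in selected
        and sum(1 for u in graph.neighbors(v) if u in selected) >= 2
    }


def hypergeom_tail_oracle(universe_size: int, set_size: int,
                          query_size: int, overlap: int) -> float:
    """P(X >= overlap) by exact enumeration of draw compositions.

    Counts the N-subsets of the universe hitting the annotated set at least
    ``overlap`` times, via the product of binomial choices — an exhaustive
    count over C(universe, query) draws without listing them.
    """
    favorable = sum(
        comb(set_size, k) * comb(universe_size - set_size, query_size - k)
        for k in range(overlap, min(set_size, query_size) + 1)
    )
    return favorable / comb(universe_size, query_size)


def hypergeom_tail_enumeration(universe: list, members: set,
                               query_size: int, overlap: int) -> float:
    """Same tail probability by literally listing every draw (small cases)."""
    hits = 0
    total = 0
    for draw in combinations(universe, query_size):
        total += 1
        if len(set(draw) & members) >= overlap:
            hits += 1
    return hits / total


def bh_oracle(p_values: list) -> list:
    """Benjamini–Hochberg step-up computed directly from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p_values[idx] * m / rank)
        adjusted[idx] = running_min
    return [min(q, 1.0) for q in adjusted]
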