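"""Brute-force reference implementations used only to check the package.

Each oracle recomputes a quantity from first principles — path enumeration,
exhaustive draws, tail minimization — independently of the code paths it
verifies.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx


def brute_betweenness(graph: nx.Graph) -> dict:
    """Betweenness by explicit enumeration of all shortest paths per pair.

    For every unordered reachable pair (s, t), all shortest s–t paths are
    enumerated from a BFS predecessor DAG and each interior vertex n is
    credited count(n)/count(total).  Normalized by (N-1)(N-2)/2.
    """
    nodes = list(graph.nodes())
    score = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(graph, s, t)
        if not paths:
            continue
        for path in paths:
            for interior in path[1:-1]:
                score[interior] += 1.0 / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2
    if norm <= 0:
        return {k: 0.0 for k in score}
    return {k: v / norm for k, v in score.items()}


def _all_shortest_paths(graph: nx.Graph, s, t) -> list[list]:
    """All shortest s–t paths via BFS levels and backward DFS."""
    dist = {s: 0}
    preds: dict = {s: []}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []
    paths: list[list] = []
    stack = [(t, [t])]
    while stack:
        node, acc = stack.pop()
        if node == s:
            paths.append(acc[::-1])
            continue
        for p in preds[node]:
            stack.append((p, acc + [p]))
    return paths


def bh_naive(p_values) -> list[float]:
    """BH step-up by explicit minimization over tail ranks."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p_values[order[j - 1]] * m / j for j in range(rank, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def s_values_by_path_enumeration(term: str, dag) -> dict[str, float]:
    """S-values as the max product of edge weights over all upward paths."""
    best = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, product = stack.pop()
        for parent, rel in dag.parents_of[node].items():
            value = product * dag.weights[rel]
            if value > best.get(parent, 0.0):
                best[parent] = value
            stack.append((parent, value))
    return best


def hypergeom_upper_tail(universe_size: int, set_size: int, query_size: int, overlap: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all possible draws."""
    universe = range(universe_size)
    members = set(range(set_size))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        if len(members & set(draw)) >= overlap:
            hits += 1
    return hits / total


def lost_pairs_by_exhaustive_check(control_pairs, case_pairs, seeds, nkpf, max_path=2):
    """All seed–nkpf pairs whose <=max_path connectivity is control-only.

    Connectivity is decided by checking every simple path of length 1 or 2
    explicitly against the pair sets.
    """

    def connected(pairs, a, b):
        pairs = {tuple(sorted(p)) for p in pairs}
        nodes = {x for p in pairs for x in p}
        if tuple(sorted((a, b))) in pairs:
            return True
        if max_path < 2:
            return False
        return any(
            tuple(sorted((a, mid))) in pairs and tuple(sorted((mid, b))) in pairs
            for mid in nodes
        )

    return {
        (s, n)
        for s in seeds
        for n in nkpf
        if connected(control_pairs, s, n) and not connected(case_pairs, s, n)
    }
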