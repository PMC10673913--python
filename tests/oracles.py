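"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive — exhaustive enumeration, double sums,
explicit pmf summation — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def modularity_double_sum(nodes, edges, partition):
    """Q = (1/2m) Σ_ij (A_ij − d_i d_j / 2m) δ(c_i, c_j) over ordered pairs."""
    adj = {(u, v) for u, v in edges} | {(v, u) for u, v in edges}
    degree = {n: 0 for n in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    m = len(edges)
    total = 0.0
    for i in nodes:
        for j in nodes:
            if partition.get(i) is None or partition.get(i) != partition.get(j):
                continue
            a_ij = 1.0 if (i, j) in adj else 0.0
            total += a_ij - degree[i] * degree[j] / (2.0 * m)
    return total / (2.0 * m)


def hypergeom_upper_tail(k, big_n, big_k, n):
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n) via pmf summation."""
    denom = math.comb(big_n, n)
    total = Fraction(0)
    for i in range(max(k, 0), min(big_k, n) + 1):
        total += Fraction(math.comb(big_k, i) * math.comb(big_n - big_k, n - i), denom)
    return float(total)


def maximal_cliques_bruteforce(nodes, edges):
    """All maximal cliques by checking every node subset."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    node_list = list(nodes)
    cliques = []
    for r in range(1, len(node_list) + 1):
        for subset in itertools.combinations(node_list, r):
            if all(b in adj[a] for a, b in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    return sorted(
        (tuple(sorted(c)) for c in cliques
         if not any(c < other for other in cliques)),
        key=lambda c: (-len(c), c),
    )


def _all_shortest_paths(adj, s, t):
    """Every shortest s→t path, found by exhaustive simple-path enumeration."""
    best: list[tuple] = []
    best_len = math.inf

    def walk(path):
        nonlocal best, best_len
        here = path[-1]
        if here == t:
            if len(path) < best_len:
                best, best_len = [tuple(path)], len(path)
            elif len(path) == best_len:
                best.append(tuple(path))
            return
        if len(path) >= best_len:
            return
        for nxt in adj[here]:
            if nxt not in path:
                walk(path + [nxt])

    walk([s])
    return best


def betweenness_path_enumeration(nodes, edges):
    """Normalized betweenness from explicit shortest-path enumeration."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    node_list = list(nodes)
    score = {n: 0.0 for n in node_list}
    for s, t in itertools.combinations(node_list, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in node_list:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    n = len(node_list)
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {v: score[v] / norm for v in node_list}


def closeness_wasserman_faust(nodes, edges):
    """Closeness with the (reachable−1)/(N−1) scaling, BFS by hand."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(list(nodes))
    result = {}
    for s in nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        reachable = len(dist)
        total = sum(dist.values())
        if reachable <= 1 or total == 0:
            result[s] = 0.0
        else:
            result[s] = ((reachable - 1) / total) * ((reachable - 1) / (n - 1))
    return result


def clique_consumer_rowscan(rows, clique_columns):
    """Count rows (dicts column→0/1) with indicator 1 for every clique member."""
    return sum(1 for row in rows if all(row[c] == 1 for c in clique_columns))


def bh_adjust(pvalues):
    """Benjamini–Hochberg step-up adjustment, spelled out."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, pvalues[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted
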