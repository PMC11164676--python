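"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a quantity by direct enumeration or a naive
running loop, sharing no code with the package's own implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def es_running_sum(stats_desc, is_hit, exponent: float = 1.0) -> float:
    """Naive weighted KS enrichment score by walking the ranking once."""
    stats_desc = np.asarray(stats_desc, dtype=float)
    is_hit = np.asarray(is_hit, dtype=bool)
    n = len(stats_desc)
    n_hits = int(is_hit.sum())
    weights = np.abs(stats_desc) ** exponent
    denom = weights[is_hit].sum()
    if denom == 0:
        weights = np.ones(n)
        denom = float(n_hits)
    running = 0.0
    best = 0.0
    for i in range(n):
        if is_hit[i]:
            running += weights[i] / denom
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def wilcoxon_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full rank-assignment enumeration.

    Valid only without ties.  Enumerates every way the x-group could occupy
    ranks of the pooled sample, computes the U statistic for each, and takes
    the probability that max(U1, U2) is at least as extreme as observed.
    Because max(U1, U2) folds both tails together, no doubling is applied.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1, n2 = len(x), len(y)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    r1 = sum(rank[v] for v in x)
    u1 = r1 - n1 * (n1 + 1) / 2
    u_obs = max(u1, n1 * n2 - u1)
    count = 0
    total = 0
    for combo in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        if max(u, n1 * n2 - u) >= u_obs:
            count += 1
        total += 1
    return min(1.0, count / total)


def betweenness_by_path_enumeration(edges) -> dict:
    """Raw betweenness by enumerating every simple path between node pairs.

    For each unordered pair, all shortest paths are found by exhaustive DFS;
    interior nodes receive 1/#shortest-paths credit.  Feasible for tiny
    graphs only.
    """
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}

    def all_paths(s, t):
        paths = []

        def dfs(v, path):
            if v == t:
                paths.append(list(path))
                return
            for w in adj[v]:
                if w not in path:
                    path.append(w)
                    dfs(w, path)
                    path.pop()

        dfs(s, [s])
        return paths

    for s, t in combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc
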