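"""Brute-force oracles for the graph measures, kept deliberately naive.

Every function here recomputes a measure from its definition (triple
loops, exhaustive enumeration) so the fast implementations in
``strokenet.metrics`` can be checked against an independent route.
"""

from __future__ import annotations

import math

import numpy as np


def floyd_warshall_oracle(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the textbook triple loop on 1/w."""
    n = adj.shape[0]
    dist = [[0.0 if i == j else (1.0 / adj[i][j] if adj[i][j] > 0 else math.inf)
             for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return np.array(dist)


def efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance, from the Floyd-Warshall oracle."""
    dist = floyd_warshall_oracle(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j != i and math.isfinite(dist[i][j]) and dist[i][j] > 0:
                total += 1.0 / dist[i][j]
        out[i] = total / (n - 1)
    return out


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    """Onnela clustering by direct triple enumeration."""
    n = adj.shape[0]
    w_max = adj.max()
    out = np.zeros(n)
    if w_max == 0:
        return out
    w = adj / w_max
    for i in range(n):
        neighbors = [j for j in range(n) if adj[i][j] > 0]
        k = len(neighbors)
        if k < 2:
            continue
        total = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = neighbors[a], neighbors[b]
                total += (w[i][j] * w[j][h] * w[h][i]) ** (1.0 / 3.0)
        out[i] = 2.0 * total / (k * (k - 1))
    return out


def local_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbour subgraph (oracle route)."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        neighbors = [j for j in range(n) if adj[i][j] > 0]
        if len(neighbors) < 2:
            continue
        sub = adj[np.ix_(neighbors, neighbors)]
        out[i] = efficiency_oracle(sub).mean()
    return out


def _all_simple_paths(adj, s, t):
    """Yield (length, intermediate nodes) of every simple s-t path."""
    n = adj.shape[0]
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, length = stack.pop()
        for v in range(n):
            if adj[node][v] > 0 and v not in path:
                new_len = length + 1.0 / adj[node][v]
                if v == t:
                    yield new_len, path[1:]
                else:
                    stack.append((v, path + [v], new_len))


def betweenness_oracle(adj: np.ndarray, rel_tol: float = 1e-9) -> np.ndarray:
    """Exhaustive-path betweenness: enumerate all simple paths per pair,
    keep the geodesics, and count pass-throughs.  Exponential; only for
    tiny graphs."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(_all_simple_paths(adj, s, t))
            if not paths:
                continue
            best = min(length for length, _ in paths)
            geodesics = [mid for length, mid in paths
                         if math.isclose(length, best, rel_tol=rel_tol)]
            sigma = len(geodesics)
            for mid in geodesics:
                for v in mid:
                    bc[v] += 1.0 / sigma
    return bc


def iter_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in iter_partitions(items[1:]):
        for k, subset in enumerate(smaller):
            yield smaller[:k] + [[first] + subset] + smaller[k + 1:]
        yield [[first]] + smaller


def modularity_q_oracle(adj: np.ndarray, blocks, gamma: float = 1.0) -> float:
    """Newman Q of a partition by direct double loop."""
    m2 = adj.sum()
    strength = adj.sum(axis=1)
    q = 0.0
    for block in blocks:
        for i in block:
            for j in block:
                q += adj[i][j] / m2 - gamma * strength[i] * strength[j] / m2**2
    return q


def best_modularity_oracle(adj: np.ndarray, gamma: float = 1.0) -> float:
    """Maximum Q over every partition (exhaustive; n <= 7 or so)."""
    n = adj.shape[0]
    return max(
        modularity_q_oracle(adj, blocks, gamma)
        for blocks in iter_partitions(list(range(n)))
    )
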