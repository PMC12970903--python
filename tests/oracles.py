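"""Independent brute-force reference implementations for graph metrics.

Deliberately naive (triple enumeration, Floyd-Warshall, exhaustive
shortest-path enumeration) so they share no code or algorithmic idea with
the package's implementations. Usable only on tiny graphs.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

INF = math.inf


def brute_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    n = adj.shape[0]
    nodal = np.zeros(n)
    for v in range(n):
        neighbors = [u for u in range(n) if adj[v, u]]
        k = len(neighbors)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(neighbors, 2) if adj[a, b])
        nodal[v] = 2.0 * links / (k * (k - 1))
    return nodal, float(nodal.mean())


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_path_length(adj: np.ndarray) -> tuple[float, np.ndarray]:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    nodal = np.zeros(n)
    total, count = 0.0, 0
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])]
        nodal[i] = sum(finite) / len(finite) if finite else 0.0
        total += sum(finite)
        count += len(finite)
    return (total / count if count else 0.0), nodal


def brute_global_efficiency(adj: np.ndarray) -> tuple[float, np.ndarray]:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    nodal = np.zeros(n)
    for i in range(n):
        nodal[i] = sum(1.0 / d[i, j] for j in range(n)
                       if j != i and math.isfinite(d[i, j])) / (n - 1)
    return float(nodal.mean()), nodal


def brute_local_efficiency(adj: np.ndarray) -> tuple[float, np.ndarray]:
    n = adj.shape[0]
    nodal = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if adj[v, u]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        nodal[v] = brute_global_efficiency(sub)[0]
    return float(nodal.mean()), nodal


def _all_shortest_paths(adj: np.ndarray, s: int, t: int,
                        target_len: float) -> list[list[int]]:
    """Every path of exactly the shortest length, by depth-limited DFS."""
    n = adj.shape[0]
    paths: list[list[int]] = []

    def dfs(node: int, path: list[int]) -> None:
        if len(path) - 1 > target_len:
            return
        if node == t:
            if len(path) - 1 == target_len:
                paths.append(list(path))
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in path:
                dfs(nxt, path + [nxt])

    dfs(s, [s])
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness; each unordered (s, t) pair counted once."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(d[s, t]) or d[s, t] == 0:
                continue
            paths = _all_shortest_paths(adj, s, t, d[s, t])
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    btw[v] += 1.0 / sigma
    return btw


def trapezoid_sum(values: np.ndarray, xs: np.ndarray) -> float:
    total = 0.0
    for i in range(len(xs) - 1):
        total += 0.5 * (values[i] + values[i + 1]) * (xs[i + 1] - xs[i])
    return total
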