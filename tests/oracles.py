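"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (triple loops, exhaustive path
enumeration, explicit tail sums) and shares no code with the
implementations it verifies.
"""

from __future__ import annotations

import math

import numpy as np


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of an adjacency matrix."""
    n = a.shape[0]
    omega = np.eye(n)
    k = [sum(a[i][u] for u in range(n)) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i][u] * a[u][j] for u in range(n))
            omega[i][j] = (l_ij + a[i][j]) / (min(k[i], k[j]) + 1.0 - a[i][j])
    return omega


def _all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Exhaustive enumeration of geodesics s -> t in a binary graph (BFS + DFS)."""
    n = a.shape[0]
    dist = [math.inf] * n
    dist[s] = 0
    queue = [s]
    while queue:
        v = queue.pop(0)
        for u in range(n):
            if a[v][u] and dist[u] is math.inf:
                dist[u] = dist[v] + 1
                queue.append(u)
    if dist[t] is math.inf:
        return []
    paths: list[list[int]] = []

    def back(v: int, suffix: list[int]) -> None:
        if v == s:
            paths.append([s] + suffix)
            return
        for u in range(n):
            if a[u][v] and dist[u] == dist[v] - 1:
                back(u, [v] + suffix)

    back(t, [])
    return paths


def betweenness_oracle(a: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Betweenness by explicit enumeration of every geodesic (ordered pairs)."""
    n = a.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = _all_shortest_paths(a, s, t)
            if not paths:
                continue
            g_total = len(paths)
            for k in range(n):
                if k in (s, t):
                    continue
                g_k = sum(1 for p in paths if k in p[1:-1])
                bc[k] += g_k / g_total
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2)
    return bc


def clustering_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop weighted clustering coefficient."""
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        numer = 0.0
        for j in range(n):
            if j == i:
                continue
            for l in range(n):
                if l in (i, j):
                    continue
                numer += a[i][j] * a[j][l] * a[l][i]
        k_i = sum(a[i][u] for u in range(n))
        denom = k_i**2 - sum(a[i][u] ** 2 for u in range(n))
        out[i] = numer / denom if denom > 0 else 0.0
    return out


def upgma_oracle(d: np.ndarray) -> list[float]:
    """Naive O(n^3) UPGMA; returns the sorted merge heights.

    Cluster distance is the mean of the original dissimilarities over all
    cross-cluster pairs (exactly what average linkage maintains).
    """
    n = d.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = (math.inf, -1, -1)
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dist = float(
                    np.mean([d[i][j] for i in clusters[x] for j in clusters[y]])
                )
                if dist < best[0]:
                    best = (dist, x, y)
        dist, x, y = best
        heights.append(dist)
        merged = clusters[x] + clusters[y]
        clusters = [c for z, c in enumerate(clusters) if z not in (x, y)]
        clusters.append(merged)
    return sorted(heights)


def hypergeom_tail_oracle(overlap: int, universe: int, set_size: int, module: int) -> float:
    """P(X >= overlap) by explicit hypergeometric tail sum with exact combinatorics."""
    total = math.comb(universe, module)
    acc = 0
    for x in range(overlap, min(set_size, module) + 1):
        acc += math.comb(set_size, x) * math.comb(universe - set_size, module - x)
    return acc / total


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass covariance / sigma Pearson correlation."""
    mx, my = x.mean(), y.mean()
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def pca_eigh_oracle(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the covariance of centered columns.

    Returns (eigenvalues descending, eigenvectors as columns).
    """
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def random_binary_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1).astype(float)
    return a + a.T


def random_weighted_adjacency(n: int, rng: np.random.Generator) -> np.ndarray:
    upper = np.triu(rng.random((n, n)), k=1)
    return upper + upper.T
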