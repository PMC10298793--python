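"""Naive reference implementations used only as independent test oracles.

Deliberately brute-force: per-source breadth-first search over adjacency
lists and exhaustive triangle enumeration, with no shared code with the
package implementations they check.
"""

from collections import deque

import numpy as np


def bfs_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in range(n):
                if a[u, v] and dist[src, v] == np.inf:
                    dist[src, v] = dist[src, u] + 1
                    q.append(v)
    return dist


def oracle_path_length(a: np.ndarray) -> float:
    dist = bfs_distances(a)
    total, count = 0.0, 0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += dist[i, j]
                count += 1
    if count == 0:
        raise ValueError("no finite distances")
    return total / count


def oracle_clustering(a: np.ndarray) -> tuple[np.ndarray, float]:
    n = a.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nbrs[x], nbrs[y]]:
                    tri += 1
        ci[i] = tri / (k * (k - 1) / 2)
    return ci, float(ci.mean())


def oracle_global_efficiency(a: np.ndarray) -> float:
    dist = bfs_distances(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def oracle_nodal_efficiency(a: np.ndarray, per_node: bool = True) -> np.ndarray:
    dist = bfs_distances(a)
    n = a.shape[0]
    el = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                el[i] += 1.0 / dist[i, j]
    return el / (n - 1) if per_node else el / (n * (n - 1))
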