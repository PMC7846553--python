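"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles on plain adjacency
matrices (no networkx), so it can serve as an independent check of the
library's graph code.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    """Unweighted shortest-path distances from one node (-1 if unreachable)."""
    n = adj.shape[0]
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in np.nonzero(adj[u])[0]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def connected_components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        dist = bfs_distances(adj, s)
        members = list(np.nonzero(dist >= 0)[0])
        seen[members] = True
        comps.append(members)
    return comps


def path_metrics_largest_component(adj: np.ndarray) -> tuple[float, int]:
    """(characteristic path length, diameter) on the largest component."""
    comps = connected_components(adj)
    comp = max(comps, key=len)
    if len(comp) < 2:
        return 0.0, 0
    sub = adj[np.ix_(comp, comp)]
    dists = []
    for s in range(len(comp)):
        d = bfs_distances(sub, s)
        dists.extend(d[s + 1 :])
    dists = np.array(dists)
    return float(dists.mean()), int(dists.max())


def average_clustering(adj: np.ndarray) -> float:
    """Mean over nodes of (closed triangles / open triples), zeros for
    degree < 2 nodes."""
    n = adj.shape[0]
    coeffs = []
    for u in range(n):
        nbrs = np.nonzero(adj[u])[0]
        k = nbrs.size
        if k < 2:
            coeffs.append(0.0)
            continue
        links = adj[np.ix_(nbrs, nbrs)].sum() / 2
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs)) if coeffs else 0.0


def all_partition_labels(n: int) -> np.ndarray:
    """All set partitions of n items as restricted-growth label rows,
    built levelwise with vectorized expansion (Bell(n) rows)."""
    labels = np.zeros((1, 1), dtype=np.int8)
    maxlab = np.zeros(1, dtype=np.int8)
    for _ in range(1, n):
        counts = maxlab.astype(np.int64) + 2
        total = int(counts.sum())
        row_idx = np.repeat(np.arange(labels.shape[0]), counts)
        starts = np.repeat(np.cumsum(counts) - counts, counts)
        newcol = (np.arange(total) - starts).astype(np.int8)
        labels = np.column_stack([labels[row_idx], newcol])
        maxlab = np.maximum(maxlab[row_idx], newcol)
    return labels


def max_modularity_exhaustive(adj: np.ndarray, batch: int = 200_000) -> float:
    """Exact maximum Newman modularity over every partition of the nodes.

    Q = sum_c (e_c / m - (d_c / 2m)^2), evaluated vectorized over batches of
    restricted-growth partition labels.  Unweighted graphs only.
    """
    n = adj.shape[0]
    edges = np.column_stack(np.nonzero(np.triu(adj)))
    m = edges.shape[0]
    if m == 0:
        return 0.0
    deg = adj.sum(axis=1)
    labels = all_partition_labels(n)
    best = -np.inf
    for start in range(0, labels.shape[0], batch):
        lab = labels[start : start + batch]
        within = np.zeros(lab.shape[0])
        for u, v in edges:
            within += lab[:, u] == lab[:, v]
        # sum_c d_c^2 = sum_{u,v} deg_u deg_v [label_u == label_v]
        dsq = np.zeros(lab.shape[0])
        for u in range(n):
            same = lab == lab[:, u][:, None]
            dsq += deg[u] * (same @ deg)
        q = within / m - dsq / (4.0 * m * m)
        best = max(best, float(q.max()))
    return best


def complete_linkage_heights(matrix: np.ndarray) -> list[float]:
    """Merge heights of naive complete-linkage agglomeration on Euclidean
    row distances (ties broken by lowest involved row index)."""
    rows = [np.asarray(r, float) for r in matrix]
    clusters: list[list[int]] = [[i] for i in range(len(rows))]
    dist = lambda i, j: float(np.linalg.norm(rows[i] - rows[j]))
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist(i, j) for i in clusters[a] for j in clusters[b])
                key = (d, min(clusters[a] + clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights
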