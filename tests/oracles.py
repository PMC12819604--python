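"""Brute-force graph oracles, independent of the package implementation.

Everything here works from first principles on small graphs: explicit
BFS distance dictionaries, triple loops over node triples for triangle
counting, and exhaustive enumeration of shortest paths for betweenness.
Deliberately slow and simple — used only to cross-check the vectorized
implementations on graphs with at most a dozen nodes.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def neighbors(A, i):
    return [j for j in range(len(A)) if A[i][j]]


def bfs_distances(A, source):
    """Plain BFS; returns dict node -> hop distance (reachable only)."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in neighbors(A, v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def oracle_degree(A):
    return [sum(1 for j in range(len(A)) if A[i][j]) for i in range(len(A))]


def oracle_clustering(A):
    """Triangle counting by a triple loop over node triples."""
    n = len(A)
    c = []
    for i in range(n):
        nb = neighbors(A, i)
        k = len(nb)
        if k < 2:
            c.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if A[nb[a]][nb[b]]
        )
        c.append(2.0 * links / (k * (k - 1)))
    return c, float(np.mean(c))


def oracle_path_length(A):
    """Mean BFS distance over reachable unordered pairs."""
    n = len(A)
    dists = []
    for s in range(n):
        d = bfs_distances(A, s)
        dists += [d[t] for t in range(s + 1, n) if t in d]
    if not dists:
        raise ValueError("no reachable pairs")
    return float(np.mean(dists))


def oracle_global_efficiency(A):
    n = len(A)
    if n < 2:
        return 0.0
    total = 0.0
    for s in range(n):
        d = bfs_distances(A, s)
        for t in range(n):
            if t != s and t in d:
                total += 1.0 / d[t]
    return total / (n * (n - 1))


def oracle_nodal_efficiency(A):
    n = len(A)
    out = []
    for s in range(n):
        d = bfs_distances(A, s)
        out.append(
            sum(1.0 / d[t] for t in range(n) if t != s and t in d) / (n - 1)
        )
    return out


def oracle_local_efficiency(A):
    n = len(A)
    eloc = []
    for i in range(n):
        nb = neighbors(A, i)
        if len(nb) < 2:
            eloc.append(0.0)
            continue
        sub = [[A[a][b] for b in nb] for a in nb]
        eloc.append(oracle_global_efficiency(sub))
    return eloc, float(np.mean(eloc))


def _all_shortest_paths(A, s, t, ds, dt):
    """Enumerate every shortest s-t path by walking the distance gradient."""
    target_len = ds[t]
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in neighbors(A, v):
            if w in ds and w in dt and ds[w] == ds[v] + 1 and ds[w] + dt[w] == target_len:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def oracle_betweenness(A):
    """Betweenness by exhaustive shortest-path enumeration.

    Each unordered pair contributes the fraction of its shortest paths
    passing through every interior node.
    """
    n = len(A)
    bc = np.zeros(n)
    dist_from = [bfs_distances(A, s) for s in range(n)]
    for s in range(n):
        for t in range(s + 1, n):
            if t not in dist_from[s]:
                continue
            paths = _all_shortest_paths(A, s, t, dist_from[s], dist_from[t])
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def oracle_auc(values, densities):
    """Trapezoid area as an explicit sum of interval midpoints."""
    total = 0.0
    for k in range(len(values) - 1):
        total += (densities[k + 1] - densities[k]) * (values[k] + values[k + 1]) / 2.0
    return total


def oracle_bh(p):
    """Benjamini-Hochberg step-up by the textbook formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def random_graph(rng, max_nodes=12):
    """A random small adjacency matrix with at least one edge."""
    while True:
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.7))
        A = np.zeros((n, n), dtype=bool)
        iu = np.triu_indices(n, 1)
        mask = rng.random(len(iu[0])) < p
        A[iu[0][mask], iu[1][mask]] = True
        A |= A.T
        if A.any():
            return A


def star_center_bc(n_leaves):
    return math.comb(n_leaves, 2)
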