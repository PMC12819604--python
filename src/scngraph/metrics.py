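"""Graph-theoretic properties of binary undirected networks.

Global measures: clustering coefficient (Watts-Strogatz nodal average),
characteristic path length (mean shortest-path distance over reachable
pairs), global and local efficiency, and the small-world triplet
(gamma, lambda, sigma) against degree-preserving rewired references.
Nodal measures: degree, nodal efficiency, and betweenness centrality,
plus the mean-normalized betweenness used by the hub rule.

Distances come from breadth-first search (scipy.sparse.csgraph);
betweenness uses Brandes' algorithm via networkx with each unordered
pair counted once and no end-point normalization.  The remaining
measures are computed directly on the adjacency matrix — the null-model
ensembles evaluate clustering and path length thousands of times, so
these hot paths stay vectorized.

Conventions for disconnected graphs: unreachable pairs are excluded from
the path-length average and contribute 1/inf = 0 to efficiencies.  The
density sweep's lower bound is chosen so networks are connected, making
this a guard rather than a common code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import GroupNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "degree",
    "clustering",
    "path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "betweenness",
    "normalize_bc",
    "random_references",
    "small_world",
    "global_metrics",
    "nodal_metrics",
    "distance_matrix",
]


def _adj(net) -> np.ndarray:
    if isinstance(net, GroupNetwork):
        return net.adjacency
    A = np.asarray(net, dtype=bool)
    return A


@dataclass(frozen=True)
class GlobalMetrics:
    clustering_coefficient: float
    path_length: float
    global_efficiency: float
    local_efficiency: float
    gamma: float = float("nan")  # Cp / <Cp_rand>
    lam: float = float("nan")  # Lp / <Lp_rand>
    sigma: float = float("nan")  # gamma / lambda


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    normalized_bc: np.ndarray


# -- distances ---------------------------------------------------------


def distance_matrix(net) -> np.ndarray:
    """All-pairs shortest-path lengths by BFS; inf for unreachable pairs."""
    A = _adj(net)
    return shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)


# -- nodal measures ----------------------------------------------------


def degree(net) -> np.ndarray:
    """Number of edges incident to each node (row sums of the adjacency)."""
    return _adj(net).sum(axis=1).astype(int)


def clustering(net) -> tuple[np.ndarray, float]:
    """Watts-Strogatz nodal clustering and its mean Cp.

    Per node: (2 x triangles through the node) / (k (k - 1)); nodes with
    fewer than two neighbours contribute 0.  Cp averages over *all*
    nodes.
    """
    A = _adj(net).astype(float)
    k = A.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", A, A, A)  # 2 x triangles per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c, float(c.mean())


def path_length(net, D: np.ndarray | None = None) -> float:
    """Mean shortest-path distance over reachable pairs (self-pairs excluded)."""
    A = _adj(net)
    if not A.any():
        raise ValueError("path length undefined for an edgeless network")
    if D is None:
        D = distance_matrix(A)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    return float(D[finite].mean())


def global_efficiency(net, D: np.ndarray | None = None) -> float:
    """Mean inverse distance over all node pairs (1/inf = 0)."""
    A = _adj(net)
    n = A.shape[0]
    if n < 2:
        return 0.0
    if D is None:
        D = distance_matrix(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(net, D: np.ndarray | None = None) -> np.ndarray:
    """E_i = mean of 1/d(i, j) over j != i."""
    A = _adj(net)
    n = A.shape[0]
    if D is None:
        D = distance_matrix(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net) -> tuple[np.ndarray, float]:
    """Per node, the global efficiency of its neighbourhood subgraph.

    Nodes with fewer than two neighbours contribute 0; Eloc is the mean
    over all nodes.
    """
    A = _adj(net)
    n = A.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if len(nb) < 2:
            continue
        eloc[i] = global_efficiency(A[np.ix_(nb, nb)])
    return eloc, float(eloc.mean())


def betweenness(net) -> np.ndarray:
    """Unnormalized shortest-path betweenness (Brandes, via networkx).

    Each unordered pair is counted once and path endpoints are excluded,
    so a star's centre over n-1 leaves scores C(n-1, 2).
    """
    A = _adj(net)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(A.shape[0])])


def normalize_bc(bc: np.ndarray) -> np.ndarray:
    """Divide by the network-mean betweenness; the output averages to 1."""
    bc = np.asarray(bc, dtype=float)
    m = bc.mean()
    if m <= 0:
        raise ValueError("mean betweenness is zero; normalized BC undefined")
    return bc / m


# -- degree-preserving null models -------------------------------------


@njit(cache=False)
def _rewire_kernel(edges, n_nodes, n_attempts, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    m = edges.shape[0]
    A = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    for k in range(m):
        A[edges[k, 0], edges[k, 1]] = True
        A[edges[k, 1], edges[k, 0]] = True
    swaps = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.random() < 0.5:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if A[a, d] or A[b, c]:
            continue
        A[a, b] = False
        A[b, a] = False
        A[c, d] = False
        A[d, c] = False
        A[a, d] = True
        A[d, a] = True
        A[b, c] = True
        A[c, b] = True
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = b, c
        swaps += 1
    return A, swaps


def random_references(net, n_refs: int = 100, seed: int = 0,
                      attempts_per_edge: int = 10) -> list[np.ndarray]:
    """Degree-preserving rewired null networks (Maslov-Sneppen swaps).

    Each reference starts from the input edge list and applies
    ``attempts_per_edge x n_edges`` double-edge-swap attempts; the degree
    sequence is invariant under every accepted swap.  Seeded and
    reproducible.  Raises if no valid swap can be found (e.g. stars or
    complete graphs, whose degree sequence admits a unique labelled
    realisation up to the blocked swaps).
    """
    A = _adj(net)
    iu, ju = np.nonzero(np.triu(A, k=1))
    m = len(iu)
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_refs)]
    refs = []
    total_swaps = 0
    for cs in child_seeds:
        edges = np.column_stack([iu, ju]).astype(np.int64)
        R, swaps = _rewire_kernel(edges, A.shape[0], attempts_per_edge * m, cs)
        total_swaps += swaps
        refs.append(np.asarray(R))
    if total_swaps == 0:
        raise ValueError(
            "rewiring found no valid double-edge swap after "
            f"{attempts_per_edge * m} attempts per reference; the graph's "
            "degree sequence admits no rewired variant"
        )
    return refs


def small_world(net, n_refs: int = 100, seed: int = 0) -> GlobalMetrics:
    """Small-world indices against a rewired ensemble.

    gamma = Cp / <Cp_ref>, lambda = Lp / <Lp_ref>, sigma = gamma/lambda.
    """
    A = _adj(net)
    D = distance_matrix(A)
    _, cp = clustering(A)
    lp = path_length(A, D)
    refs = random_references(A, n_refs=n_refs, seed=seed)
    cp_ref = np.array([clustering(R)[1] for R in refs])
    lp_ref = np.array([path_length(R) for R in refs])
    if cp_ref.mean() <= 0:
        raise ValueError("mean reference clustering is zero; gamma undefined")
    gamma = cp / cp_ref.mean()
    lam = lp / lp_ref.mean()
    return GlobalMetrics(
        clustering_coefficient=cp,
        path_length=lp,
        global_efficiency=global_efficiency(A, D),
        local_efficiency=local_efficiency(A)[1],
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
    )


# -- bundles -----------------------------------------------------------


def global_metrics(net, n_refs: int | None = None, seed: int = 0) -> GlobalMetrics:
    """All global measures; with ``n_refs`` the small-world triplet too."""
    if n_refs:
        return small_world(net, n_refs=n_refs, seed=seed)
    A = _adj(net)
    D = distance_matrix(A)
    return GlobalMetrics(
        clustering_coefficient=clustering(A)[1],
        path_length=path_length(A, D),
        global_efficiency=global_efficiency(A, D),
        local_efficiency=local_efficiency(A)[1],
    )


def nodal_metrics(net) -> NodalMetrics:
    A = _adj(net)
    D = distance_matrix(A)
    bc = betweenness(A)
    return NodalMetrics(
        degree=degree(A),
        nodal_efficiency=nodal_efficiency(A, D),
        betweenness=bc,
        normalized_bc=normalize_bc(bc) if bc.mean() > 0 else np.zeros_like(bc),
    )
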