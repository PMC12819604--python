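"""Group-level structural covariance network construction.

For each group, the Pearson correlation between every pair of regions'
corrected volumes gives a 90 x 90 association matrix.  Negative
correlations are zeroed (edges are positive covariance only), and the
matrix is binarized at a *fixed sparsity*: the K strongest positive
correlations become edges, K = floor(density * R(R-1)/2), so both
groups' networks carry exactly the same number of edges at every density
of the sweep (0.10 to 0.50 in steps of 0.02 by default).

Ties at the K-th rank are broken by (row, column) index order, which
makes the construction deterministic and the edge sets nested across the
sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CorrelationMatrix",
    "GroupNetwork",
    "density_sweep",
    "correlation_matrix",
    "zero_negatives",
    "binarize_at_density",
    "min_connected_density",
    "n_edges_at_density",
    "ranked_edges",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with a zero diagonal."""

    values: np.ndarray = field(repr=False)
    group: str = ""
    n_subjects: int = 0
    region_names: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlation values must lie in [-1, 1]")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GroupNetwork:
    """Binary undirected network at one density of the sweep."""

    adjacency: np.ndarray = field(repr=False)
    density: float = float("nan")
    group: str = ""
    region_names: tuple[str, ...] | None = None

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        object.__setattr__(self, "adjacency", A)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def is_connected(self) -> bool:
        n, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n == 1


def density_sweep(d_min: float = 0.10, d_max: float = 0.50, step: float = 0.02) -> np.ndarray:
    """The ordered density grid (default 0.10, 0.12, ..., 0.50; 21 values)."""
    if not (0 < d_min < d_max < 1) or step <= 0:
        raise ValueError("need 0 < d_min < d_max < 1 and step > 0")
    n = int(round((d_max - d_min) / step))
    grid = np.round(d_min + step * np.arange(n + 1), 10)
    return grid[grid <= d_max + 1e-12]


def n_edges_at_density(n_regions: int, density: float) -> int:
    """K = floor(density * R(R-1)/2) — the fixed edge budget at a density."""
    return int(np.floor(density * n_regions * (n_regions - 1) / 2 + 1e-9))


def correlation_matrix(
    residuals: pd.DataFrame,
    group: str,
    region_columns: list[str] | None = None,
) -> CorrelationMatrix:
    """Pearson correlations between regions across one group's subjects."""
    sub = residuals[residuals["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group '{group}' has {len(sub)} subjects; need >= 3")
    if region_columns is None:
        from .residualize import DEFAULT_COVARIATES

        meta = {"subject_id", "group", *DEFAULT_COVARIATES, "psqi"}
        region_columns = [c for c in residuals.columns if c not in meta]
    X = sub[region_columns].to_numpy(dtype=float)
    sd = X.std(axis=0)
    dead = [region_columns[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance regions in group '{group}': {dead}")
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 0.0)
    return CorrelationMatrix(C, group=group, n_subjects=len(sub),
                             region_names=tuple(region_columns))


def zero_negatives(corr: CorrelationMatrix) -> CorrelationMatrix:
    """Retain positive correlations only; non-positive entries become 0."""
    v = np.where(corr.values > 0, corr.values, 0.0)
    return CorrelationMatrix(v, group=corr.group, n_subjects=corr.n_subjects,
                             region_names=corr.region_names)


def ranked_edges(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs with positive weight, strongest first.

    Ties are kept in row-major (i, j) order (stable sort), the
    deterministic tie-break that makes edge sets nested across densities.
    Returns (rows, cols) arrays of equal length.
    """
    R = values.shape[0]
    iu, ju = np.triu_indices(R, k=1)
    w = values[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.argsort(-w, kind="stable")
    return iu[order], ju[order]


def binarize_at_density(corr: CorrelationMatrix, density: float) -> GroupNetwork:
    """Keep the K strongest positive correlations as binary edges."""
    if not (0 < density < 1):
        raise ValueError("density must be in (0, 1)")
    R = corr.n_regions
    K = n_edges_at_density(R, density)
    ri, rj = ranked_edges(corr.values)
    if len(ri) < K:
        max_density = len(ri) / (R * (R - 1) / 2)
        raise ValueError(
            f"only {len(ri)} positive correlations available; cannot reach "
            f"density {density} (K={K}); maximum achievable density is "
            f"{max_density:.4f}"
        )
    A = np.zeros((R, R), dtype=bool)
    A[ri[:K], rj[:K]] = True
    A |= A.T
    return GroupNetwork(A, density=density, group=corr.group,
                        region_names=corr.region_names)


def min_connected_density(
    corr_a: CorrelationMatrix,
    corr_b: CorrelationMatrix,
    sweep: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Smallest sweep density at which both groups' networks are connected.

    Returns the density and a per-density diagnostics table (number of
    connected components per group).  Raises if no sweep density connects
    both networks, listing the regions left isolated at the maximum
    density.
    """
    if sweep is None:
        sweep = density_sweep()
    rows = []
    found = None
    for d in sweep:
        comps = {}
        for corr in (corr_a, corr_b):
            net = binarize_at_density(corr, d)
            ncomp, _ = connected_components(csr_matrix(net.adjacency), directed=False)
            comps[corr.group or "?"] = ncomp
        rows.append({"density": float(d), **{f"n_components_{g}": c for g, c in comps.items()}})
        if found is None and all(c == 1 for c in comps.values()):
            found = float(d)
    diag = pd.DataFrame(rows)
    if found is None:
        isolated = []
        for corr in (corr_a, corr_b):
            net = binarize_at_density(corr, sweep[-1])
            deg = net.adjacency.sum(axis=0)
            names = corr.region_names or tuple(map(str, range(corr.n_regions)))
            _, labels = connected_components(csr_matrix(net.adjacency), directed=False)
            main = np.bincount(labels).argmax()
            isolated += [names[i] for i in np.flatnonzero(labels != main)]
        raise ValueError(
            f"no density in the sweep connects both networks; disconnected "
            f"regions at density {sweep[-1]}: {sorted(set(isolated))}"
        )
    if found > sweep[0]:
        warnings.warn(
            f"networks only connect from density {found}; sweep starts at {sweep[0]}",
            stacklevel=2,
        )
    return found, diag
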