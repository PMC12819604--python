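"""Group inference over the density sweep.

Every metric is evaluated at all 21 densities of the sweep and summarised
by its area under the curve (AUC, trapezoidal), a threshold-free scalar
per metric and node.  Group differences of these AUCs are tested by
label permutation: group labels are shuffled (group sizes preserved) and
the full network pipeline — correlation, positive-edge thresholding,
binarization, metrics, AUC — is rebuilt per permutation.  Nodal p-values
are corrected across the 90 regions within each metric family by
Benjamini-Hochberg FDR; the five global metrics are reported raw.

Hubs are nodes whose mean-normalized betweenness centrality, averaged
over the sweep via AUC / (d_max - d_min), exceeds the network mean by
more than one (sample) standard deviation.

Covariate regression is fitted once on the pooled sample before
permutation: the covariate model carries no group term, so residual rows
are exchangeable under the null and refitting per shuffle would change
nothing (``repermute_residuals=True`` forces the refit; it matters only
for per-group residualization).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import Atlas
from .metrics import (
    betweenness,
    clustering,
    distance_matrix,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    normalize_bc,
    path_length,
    random_references,
)
from .network import n_edges_at_density, ranked_edges, density_sweep
from .residualize import residualize, DEFAULT_COVARIATES

__all__ = [
    "NODAL_METRICS",
    "GLOBAL_METRICS",
    "metric_curves",
    "auc",
    "auc_table",
    "permutation_test",
    "fdr_correct",
    "identify_hubs",
    "normalized_bc_profile",
    "region_columns_of",
]

NODAL_METRICS = ("degree", "nodal_efficiency", "betweenness")
GLOBAL_METRICS = ("clustering", "path_length", "global_efficiency",
                  "local_efficiency", "sigma")
GROUPS = ("patient", "control")


def region_columns_of(df: pd.DataFrame) -> list[str]:
    meta = {"subject_id", "group", *DEFAULT_COVARIATES, "psqi"}
    return [c for c in df.columns if c not in meta]


def _curves_from_matrix(
    X: np.ndarray,
    sweep: np.ndarray,
    metrics: tuple[str, ...],
    n_refs: int = 0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Metric curves for one group's residual matrix (subjects x regions).

    Returns nodal metrics as (R, n_densities) arrays and global metrics as
    (n_densities,) arrays.  Requesting ``sigma`` also yields ``gamma`` and
    ``lambda`` and requires ``n_refs`` rewired references per density.
    """
    unknown = set(metrics) - set(NODAL_METRICS) - set(GLOBAL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if "sigma" in metrics and n_refs < 1:
        raise ValueError("sigma requires n_refs >= 1 rewired references")

    R = X.shape[1]
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 0.0)
    ri, rj = ranked_edges(C)
    Ks = [n_edges_at_density(R, d) for d in sweep]
    if Ks[-1] > len(ri):
        max_d = len(ri) / (R * (R - 1) / 2)
        raise ValueError(
            f"only {len(ri)} positive correlations; cannot reach density "
            f"{sweep[-1]} (max achievable {max_d:.4f})"
        )

    nd = len(sweep)
    out: dict[str, np.ndarray] = {}
    for m in metrics:
        out[m] = np.zeros((R, nd)) if m in NODAL_METRICS else np.zeros(nd)
    if "sigma" in metrics:
        out["gamma"] = np.zeros(nd)
        out["lambda"] = np.zeros(nd)

    degree_only = set(metrics) == {"degree"}
    need_D = bool(
        {"nodal_efficiency", "path_length", "global_efficiency", "sigma"} & set(metrics)
    )
    A = None if degree_only else np.zeros((R, R), dtype=bool)
    prev_k = 0
    ss = np.random.SeedSequence(seed)
    density_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(nd)]
    deg = np.zeros(R, dtype=int)
    for di, K in enumerate(Ks):
        new_i, new_j = ri[prev_k:K], rj[prev_k:K]
        if A is None:
            np.add.at(deg, new_i, 1)
            np.add.at(deg, new_j, 1)
        else:
            A[new_i, new_j] = True
            A[new_j, new_i] = True
        prev_k = K
        if "degree" in metrics:
            out["degree"][:, di] = deg if A is None else A.sum(axis=1)
        if A is None:
            continue
        D = distance_matrix(A) if need_D else None
        if "nodal_efficiency" in metrics:
            out["nodal_efficiency"][:, di] = nodal_efficiency(A, D)
        if "betweenness" in metrics:
            out["betweenness"][:, di] = betweenness(A)
        if "clustering" in metrics or "sigma" in metrics:
            cp = clustering(A)[1]
            if "clustering" in metrics:
                out["clustering"][di] = cp
        if "path_length" in metrics or "sigma" in metrics:
            lp = path_length(A, D if D is not None else None)
            if "path_length" in metrics:
                out["path_length"][di] = lp
        if "global_efficiency" in metrics:
            out["global_efficiency"][di] = global_efficiency(A, D)
        if "local_efficiency" in metrics:
            out["local_efficiency"][di] = local_efficiency(A)[1]
        if "sigma" in metrics:
            refs = random_references(A, n_refs=n_refs, seed=density_seeds[di])
            cp_ref = float(np.mean([clustering(Rf)[1] for Rf in refs]))
            lp_ref = float(np.mean([path_length(Rf) for Rf in refs]))
            if cp_ref <= 0:
                raise ValueError("mean reference clustering is zero; gamma undefined")
            gamma = cp / cp_ref
            lam = lp / lp_ref
            out["gamma"][di] = gamma
            out["lambda"][di] = lam
            out["sigma"][di] = gamma / lam
    return out


def metric_curves(
    residuals: pd.DataFrame,
    sweep: np.ndarray | None = None,
    metrics: tuple[str, ...] = NODAL_METRICS + GLOBAL_METRICS,
    n_refs: int = 100,
    seed: int = 0,
    region_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of metric values per group, node and density.

    Columns: ``group, metric, node, density, value`` with ``node`` set to
    region names for nodal metrics and ``"global"`` otherwise.  Warns if
    either group's network is disconnected at the sweep minimum.
    """
    if sweep is None:
        sweep = density_sweep()
    if region_columns is None:
        region_columns = region_columns_of(residuals)
    rows = []
    ss = np.random.SeedSequence(seed)
    for group, gseed in zip(GROUPS, ss.spawn(len(GROUPS))):
        sub = residuals[residuals["group"] == group]
        if sub.empty:
            raise ValueError(f"no subjects in group '{group}'")
        X = sub[region_columns].to_numpy(dtype=float)
        curves = _curves_from_matrix(
            X, sweep, tuple(metrics), n_refs=n_refs,
            seed=int(gseed.generate_state(1)[0] % (2**31)),
        )
        from .network import CorrelationMatrix, binarize_at_density

        Cg = np.corrcoef(X, rowvar=False)
        Cg = np.clip((Cg + Cg.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(Cg, 0.0)
        net_min = binarize_at_density(
            CorrelationMatrix(Cg, group=group), float(sweep[0])
        )
        if not net_min.is_connected():
            warnings.warn(
                f"group '{group}' network disconnected at sweep minimum "
                f"{sweep[0]}", stacklevel=2,
            )
        for m, vals in curves.items():
            if vals.ndim == 2:
                for r, name in enumerate(region_columns):
                    for d, v in zip(sweep, vals[r]):
                        rows.append((group, m, name, float(d), float(v)))
            else:
                for d, v in zip(sweep, vals):
                    rows.append((group, m, "global", float(d), float(v)))
    out = pd.DataFrame(rows, columns=["group", "metric", "node", "density", "value"])
    return out


def auc(values: np.ndarray, densities: np.ndarray) -> float:
    """Trapezoidal area under a metric curve over the density axis."""
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if len(values) < 2 or len(values) != len(densities):
        raise ValueError("need >= 2 aligned (density, value) points")
    return float(np.trapezoid(values, densities))


def auc_table(curves: pd.DataFrame) -> pd.DataFrame:
    """AUC summary of a tidy curve table: one row per group/metric/node."""
    rows = []
    for (group, metric, node), sub in curves.groupby(
        ["group", "metric", "node"], sort=False
    ):
        sub = sub.sort_values("density")
        rows.append(
            (group, metric, node, auc(sub["value"].to_numpy(), sub["density"].to_numpy()))
        )
    return pd.DataFrame(rows, columns=["group", "metric", "node", "auc"])


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _auc_diffs(
    X: np.ndarray,
    labels: np.ndarray,
    sweep: np.ndarray,
    metrics: tuple[str, ...],
    n_refs: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """patient-minus-control AUC per metric (vector for nodal, scalar for global)."""
    diffs = {}
    curves = {}
    ss = np.random.SeedSequence(seed)
    for group, gs in zip(GROUPS, ss.spawn(2)):
        curves[group] = _curves_from_matrix(
            X[labels == group], sweep, metrics, n_refs=n_refs,
            seed=int(gs.generate_state(1)[0] % (2**31)),
        )
    for m in curves[GROUPS[0]]:
        a_p = np.trapezoid(curves["patient"][m], sweep, axis=-1)
        a_c = np.trapezoid(curves["control"][m], sweep, axis=-1)
        diffs[m] = a_p - a_c
    return diffs


def permutation_test(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    sweep: np.ndarray | None = None,
    metrics: tuple[str, ...] = NODAL_METRICS,
    n_perm: int = 1000,
    seed: int = 0,
    scope: str = "pooled",
    repermute_residuals: bool = False,
    n_refs: int = 0,
    region_columns: list[str] | None = None,
    return_null: bool = False,
):
    """Label-permutation test of group AUC differences.

    For every metric (and region, for nodal metrics) the observed
    patient-minus-control AUC difference is compared with a null sample
    obtained by shuffling group labels ``n_perm`` times, rebuilding the
    networks and metrics per shuffle.  Two-sided p-values use the add-one
    rule p = (#{|null| >= |obs|} + 1) / (n_perm + 1); nodal families get
    BH-FDR q-values across regions.

    Returns a DataFrame (metric, node, observed_diff, p_value, q_value),
    plus the raw null samples if ``return_null``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 19:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve p below {1 / (n_perm + 1):.3f}; "
            "alpha=0.05 decisions are unreliable", stacklevel=2,
        )
    if sweep is None:
        sweep = density_sweep()
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    if region_columns is None:
        region_columns = region_columns_of(cohort)
    labels = cohort["group"].to_numpy()
    for g in GROUPS:
        if (labels == g).sum() == 0:
            raise ValueError(f"no subjects in group '{g}'")
    metrics = tuple(metrics)

    rng = np.random.default_rng(seed)
    refit = repermute_residuals or scope == "per-group"

    def residual_matrix(lbl):
        df = cohort.copy()
        df["group"] = lbl
        res = residualize(df, covariates, scope=scope, region_columns=region_columns)
        return res[region_columns].to_numpy(dtype=float)

    X0 = residual_matrix(labels)
    sub_seed = int(rng.integers(2**31))
    observed = _auc_diffs(X0, labels, sweep, metrics, n_refs, sub_seed)

    null: dict[str, list] = {m: [] for m in observed}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        Xp = residual_matrix(perm) if refit else X0
        d = _auc_diffs(Xp, perm, sweep, metrics, n_refs, sub_seed)
        for m in null:
            null[m].append(d[m])

    rows = []
    for m in observed:
        nul = np.asarray(null[m])  # (n_perm, R) or (n_perm,)
        obs = observed[m]
        count = np.sum(np.abs(nul) >= np.abs(obs), axis=0)
        p = (count + 1) / (n_perm + 1)
        if np.ndim(obs) > 0:
            q = fdr_correct(p)
            for r, name in enumerate(region_columns):
                rows.append((m, name, float(obs[r]), float(p[r]), float(q[r])))
        else:
            rows.append((m, "global", float(obs), float(p), float("nan")))
    result = pd.DataFrame(
        rows, columns=["metric", "node", "observed_diff", "p_value", "q_value"]
    )
    if return_null:
        return result, {m: np.asarray(v) for m, v in null.items()}
    return result


def normalized_bc_profile(curves: pd.DataFrame, group: str) -> pd.Series:
    """Density-averaged normalized betweenness per region for one group.

    At each density the betweenness vector is divided by its network
    mean; the resulting curve is summarised by AUC / (d_max - d_min), a
    density-weighted average that inherits mean ~= 1 across regions.
    """
    sub = curves[(curves["group"] == group) & (curves["metric"] == "betweenness")]
    if sub.empty:
        raise ValueError(f"no betweenness curves for group '{group}'")
    wide = sub.pivot(index="node", columns="density", values="value")
    densities = wide.columns.to_numpy(dtype=float)
    norm = wide.to_numpy() / wide.to_numpy().mean(axis=0, keepdims=True)
    profile = np.trapezoid(norm, densities, axis=1) / (densities[-1] - densities[0])
    return pd.Series(profile, index=wide.index, name="normalized_bc")


def identify_hubs(
    normalized_bc: pd.Series | np.ndarray,
    atlas: Atlas | None = None,
    group: str = "",
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Hub table by the mean + 1 SD rule on normalized betweenness.

    A region is a hub iff its value strictly exceeds mean + 1 x SD
    (sample SD by default).  A constant profile has SD 0 and therefore no
    hubs.  The rule is translation- and scale-invariant in the hub set.
    """
    if isinstance(normalized_bc, pd.Series):
        values = normalized_bc.to_numpy(dtype=float)
        names = list(normalized_bc.index)
    else:
        values = np.asarray(normalized_bc, dtype=float)
        names = (
            atlas.names if atlas is not None else [str(i) for i in range(len(values))]
        )
    sd = values.std(ddof=sd_ddof)
    if sd == 0:
        warnings.warn("normalized BC has zero variance; no hubs identified",
                      stacklevel=2)
    threshold = values.mean() + sd
    lobes = atlas.lobes if atlas is not None else None
    out = pd.DataFrame(
        {
            "region": names,
            "group": group,
            "lobe": [lobes.get(n, "") for n in names] if lobes is not None else "",
            "normalized_bc": values,
            "threshold": threshold,
            "is_hub": values > threshold,
        }
    )
    return out
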