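"""ROI-level morphometric statistics.

Two analyses, both general linear models fitted per region:

* **group contrast** — volume ~ intercept + group + covariates, with a
  t-test on the group coefficient and Cohen's d computed as the
  covariate-adjusted group difference divided by the pooled residual SD
  (sqrt of the model's mean squared error);
* **PSQI regression** — within patients only, volume ~ intercept + PSQI
  + covariates, with a t-test on the PSQI slope.

This is the region-table analog of a voxelwise analysis: per-region
uncorrected p-values plus an optional BH-FDR column.  It is *not*
equivalent to voxel-cluster inference — there are no voxels, clusters or
family-wise error correction here, and effect sizes are per-region, not
per-peak-voxel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import fdr_correct, region_columns_of
from .residualize import DEFAULT_COVARIATES, _check_full_rank

__all__ = ["group_contrast", "psqi_regression"]


def _glm_tstats(X: np.ndarray, Y: np.ndarray, coef_index: int):
    """Per-region t, p and coefficient for one design column.

    X is the common (n x p) design, Y the (n x R) outcome block; returns
    (beta, t, p, sqrt_mse) vectors of length R.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (p, R)
    resid = Y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    mse = (resid**2).sum(axis=0) / df
    se = np.sqrt(mse * XtX_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef_index] / se, np.inf * np.sign(beta[coef_index]))
    pval = 2 * stats.t.sf(np.abs(t), df)
    return beta[coef_index], t, np.clip(pval, np.finfo(float).tiny, 1.0), np.sqrt(mse)


def group_contrast(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    region_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Patient-vs-control GLM contrast per region, with Cohen's d.

    Returns a DataFrame (region, contrast, t, p, q, cohens_d, direction);
    direction is "patient>control" or "patient<control" by the sign of
    the adjusted difference.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    for g in ("patient", "control"):
        if (cohort["group"] == g).sum() < 2:
            raise ValueError(f"group '{g}' needs >= 2 subjects")
    if region_columns is None:
        region_columns = region_columns_of(cohort)
    g = (cohort["group"] == "patient").to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(cohort)), g]
        + [np.asarray(cohort[c], dtype=float) for c in covariates]
    )
    _check_full_rank(X, ["group"] + list(covariates))
    Y = cohort[region_columns].to_numpy(dtype=float)
    beta, t, p, pooled_sd = _glm_tstats(X, Y, coef_index=1)
    d = beta / pooled_sd
    out = pd.DataFrame(
        {
            "region": region_columns,
            "contrast": "group",
            "t": t,
            "p": p,
            "q": fdr_correct(p),
            "cohens_d": d,
            "direction": np.where(beta >= 0, "patient>control", "patient<control"),
        }
    )
    return out


def psqi_regression(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    region_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Within-patient multiple regression of volume on the PSQI score."""
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    patients = cohort[cohort["group"] == "patient"]
    if patients.empty:
        raise ValueError("no patients in cohort")
    if patients["psqi"].nunique() < 2:
        raise ValueError("PSQI is constant among patients; slope undefined")
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    if region_columns is None:
        region_columns = region_columns_of(cohort)
    X = np.column_stack(
        [np.ones(len(patients)), np.asarray(patients["psqi"], dtype=float)]
        + [np.asarray(patients[c], dtype=float) for c in covariates]
    )
    _check_full_rank(X, ["psqi"] + list(covariates))
    Y = patients[region_columns].to_numpy(dtype=float)
    beta, t, p, _ = _glm_tstats(X, Y, coef_index=1)
    out = pd.DataFrame(
        {
            "region": region_columns,
            "contrast": "psqi",
            "t": t,
            "p": p,
            "q": fdr_correct(p),
            "cohens_d": np.nan,
            "direction": np.where(beta >= 0, "positive", "negative"),
            "slope": beta,
        }
    )
    return out
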