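"""Covariate removal: per-region linear regression of volume on confounds.

Each region's volumes are regressed on an intercept plus the chosen
covariates by ordinary least squares, and the residuals ("corrected
GMV") replace the volumes.  The correlation network downstream is built
from these residuals, so anything captured by the design matrix (head
size, age, mood scores, ...) cannot masquerade as structural covariance.

By default the model is fitted on the pooled sample without a group
term: group-related volume differences survive into the residuals while
nuisance effects are removed.  ``scope="per-group"`` fits the covariate
model separately within each group instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["residualize", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ["hama", "hamd", "tiv", "age", "sex", "education"]


def _design(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(df))] + [np.asarray(df[c], dtype=float) for c in covariates]
    )
    return X


def _check_full_rank(X: np.ndarray, covariates: list[str]) -> None:
    # QR with pivoting: columns pivoted past the numerical rank are the
    # collinear ones we can name.
    _, Rm, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rm))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        names = ["intercept"] + list(covariates)
        collinear = [names[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )


def _ols_residuals(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def residualize(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    scope: str = "pooled",
    region_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Regress covariates out of every region column.

    Parameters
    ----------
    cohort
        Cohort table with ``subject_id``, ``group``, covariate columns and
        region volume columns.
    covariates
        Ordered covariate names; default is the six-confound set
        (HAMA, HAMD, TIV, age, sex, education).  An empty list fits the
        intercept only, i.e. mean-centres each region.
    scope
        ``"pooled"`` (default) fits one model over both groups;
        ``"per-group"`` fits within each group separately.
    region_columns
        Explicit region columns; default = every column after the known
        metadata/covariate columns.

    Returns
    -------
    DataFrame with the same rows and layout, volumes replaced by OLS
    residuals (zero mean per region within the fitted sample).
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    if scope not in ("pooled", "per-group"):
        raise ValueError("scope must be 'pooled' or 'per-group'")
    if region_columns is None:
        meta = {"subject_id", "group", *DEFAULT_COVARIATES, "psqi"}
        region_columns = [c for c in cohort.columns if c not in meta]
    if not region_columns:
        raise ValueError("no region columns found")

    Y = cohort[region_columns].to_numpy(dtype=float)
    sd = Y.std(axis=0, ddof=1)
    zero_var = [region_columns[i] for i in np.flatnonzero(sd == 0)]
    if zero_var:
        raise ValueError(f"zero-variance regions cannot be residualized: {zero_var}")

    resid = np.empty_like(Y)
    if scope == "pooled":
        X = _design(cohort, covariates)
        _check_full_rank(X, covariates)
        resid[:] = _ols_residuals(X, Y)
    else:
        for _, idx in cohort.groupby("group", sort=False).indices.items():
            sub = cohort.iloc[idx]
            X = _design(sub, covariates)
            _check_full_rank(X, covariates)
            resid[idx] = _ols_residuals(X, Y[idx])

    out = cohort.copy()
    out[region_columns] = resid
    return out
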