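"""Confounder correction: per-gene regression and residual extraction.

First step of the two-step network inference procedure.  Count (sequencing)
data are modelled per gene i by Poisson regression with a library-size
offset,

    Y_ij ~ Poisson(lambda_ij),
    log(lambda_ij) = log(n_j) + x_j' beta_i,

with n_j the total number of counts in sample j and x_j the sample
covariates (age, sex, BMI, glucose, smoking and the technical GC-content
covariate).  Deviance residuals

    d_ij = sign(y_ij - lam_ij) * sqrt(2 y_ij log(y_ij/lam_ij) - 2 (y_ij - lam_ij))

are approximately standard normal and feed the Gaussian graphical model.
Continuous (microarray-like) data use ordinary least squares on the same
covariates minus the count-specific ones (GC, library size).

Residuals can optionally be standardised per gene to mean 0 / variance 1
(n-1 denominator); whether this scaling is applied is the central analysis
choice studied downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla

#: covariates entering the count-platform design (offset handled separately)
COUNT_COVARIATES = ["age", "sex", "bmi", "glucose", "smoking", "gc"]
#: technical covariates always corrected for counts, even in the
#: "no confounder correction" analysis arm
COUNT_TECHNICAL = ["gc"]
#: covariates entering the continuous-platform design
CONTINUOUS_COVARIATES = ["age", "sex", "bmi", "glucose", "smoking"]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50
_ETA_CAP = 30.0


@dataclass
class RegressionFit:
    """Per-gene regression result on the link scale."""

    coefficients: pd.Series
    fitted: np.ndarray
    deviance: float | None
    converged: bool
    iterations: int
    gene_id: str | None = None


@dataclass
class ResidualMatrix:
    """Gene-by-sample residuals ready for network inference."""

    values: pd.DataFrame
    standardized: bool
    platform: str


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def build_design(covariates: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Intercept-first design matrix from named covariate columns."""
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate table lacks columns: {missing}")
    X = pd.DataFrame(
        {"intercept": np.ones(len(covariates))}, index=covariates.index
    )
    for c in columns:
        X[c] = pd.to_numeric(covariates[c]).to_numpy(dtype=float)
    return X


def _check_full_rank(X: pd.DataFrame) -> np.ndarray:
    A = X.to_numpy(dtype=float)
    k = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    if rank < k:
        # QR with column pivoting: pivots beyond the rank are the collinear set
        _, _, piv = sla.qr(A, pivoting=True, mode="economic")
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear columns: {bad}"
        )
    return A


# ---------------------------------------------------------------------------
# Poisson GLM by IRLS
# ---------------------------------------------------------------------------

def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum[y log(y/mu) - (y - mu)], with y log(y/mu) = 0 at y = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_poisson_glm(
    y,
    covariates: pd.DataFrame,
    offset=None,
    *,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
    gene_id: str | None = None,
) -> RegressionFit:
    """Poisson log-link regression with a fixed offset, by IRLS.

    ``covariates`` is the design matrix without intercept column names
    resolved — any DataFrame is used as-is after prepending an intercept if
    one is not present.  ``offset`` is log n_j (default 0).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("count response must contain non-negative integers")
    if isinstance(covariates, pd.DataFrame):
        X_df = covariates.copy()
        if "intercept" not in X_df.columns:
            X_df.insert(0, "intercept", 1.0)
    else:
        arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        if arr.shape[0] != len(y):
            arr = arr.T
        X_df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
        X_df.insert(0, "intercept", 1.0)
    X = _check_full_rank(X_df)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("response and design lengths differ")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(k)
    beta[0] = np.log(y.mean() + 0.5)
    dev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + off, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        W = mu
        z = (eta - off) + (y - mu) / mu
        XtW = X.T * W
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        new_dev = poisson_deviance(y, np.exp(np.clip(X @ beta + off,
                                                     -_ETA_CAP, _ETA_CAP)))
        if abs(dev - new_dev) <= tol * (0.1 + abs(new_dev)):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged:
        warnings.warn(
            f"Poisson IRLS did not converge in {max_iter} iterations"
            + (f" (gene {gene_id})" if gene_id else ""),
            RuntimeWarning,
        )
    mu = np.exp(np.clip(X @ beta + off, -_ETA_CAP, _ETA_CAP))
    return RegressionFit(
        coefficients=pd.Series(beta, index=list(X_df.columns)),
        fitted=mu,
        deviance=dev,
        converged=converged,
        iterations=it,
        gene_id=gene_id,
    )


def deviance_residuals(y, mu) -> np.ndarray:
    """Signed square-root deviance contributions of a Poisson fit."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("fitted means must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    inner = 2.0 * term - 2.0 * (y - mu)
    inner = np.clip(inner, 0.0, None)  # guard float noise at y ~= mu
    return np.sign(y - mu) * np.sqrt(inner)


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------

def fit_linear_model(
    y,
    covariates: pd.DataFrame,
    *,
    gene_id: str | None = None,
) -> RegressionFit:
    """Ordinary least squares with intercept; residuals = y - fitted."""
    y = np.asarray(y, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        X_df = covariates.copy()
        if "intercept" not in X_df.columns:
            X_df.insert(0, "intercept", 1.0)
    else:
        arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        if arr.shape[0] != len(y):
            arr = arr.T
        X_df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
        X_df.insert(0, "intercept", 1.0)
    X = _check_full_rank(X_df)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return RegressionFit(
        coefficients=pd.Series(beta, index=list(X_df.columns)),
        fitted=fitted,
        deviance=None,
        converged=True,
        iterations=1,
        gene_id=gene_id,
    )


# ---------------------------------------------------------------------------
# standardisation and the full residual pipeline
# ---------------------------------------------------------------------------

def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (row) centring and scaling to unit variance (n-1 denominator)."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        genes = [str(matrix.index[i]) for i in bad[:5]]
        raise ValueError(f"constant rows cannot be standardised: {genes}")
    out = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def residual_pipeline(
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    platform: str,
    *,
    scale: bool = True,
    correct_confounders: bool = True,
) -> ResidualMatrix:
    """Regress out covariates per gene and return the residual matrix.

    For counts, a Poisson GLM with log library-size offset is fitted per
    gene and deviance residuals are extracted; the technical covariates (GC
    content) and the offset are retained even when ``correct_confounders``
    is False.  For continuous data OLS residuals are used; with
    ``correct_confounders=False`` the raw expression passes through
    unregressed.  ``scale=True`` standardises each gene to mean 0 /
    variance 1.
    """
    if platform not in ("counts", "continuous"):
        raise ValueError("platform must be 'counts' or 'continuous'")
    if list(expression.columns) != list(covariates.index):
        if set(expression.columns) != set(covariates.index):
            raise ValueError("expression samples do not match covariate rows")
        covariates = covariates.loc[expression.columns]

    if platform == "counts":
        cols = COUNT_COVARIATES if correct_confounders else COUNT_TECHNICAL
        if "library_size" not in covariates.columns:
            raise KeyError("count covariates must include library_size")
        offset = np.log(pd.to_numeric(covariates["library_size"])
                        .to_numpy(dtype=float))
        X = build_design(covariates, cols)
        resid = np.empty(expression.shape)
        for i, gene in enumerate(expression.index):
            y = expression.iloc[i].to_numpy(dtype=float)
            fit = fit_poisson_glm(y, X, offset, gene_id=str(gene))
            resid[i] = deviance_residuals(y, fit.fitted)
        out = pd.DataFrame(resid, index=expression.index,
                           columns=expression.columns)
    else:
        if correct_confounders:
            X = build_design(covariates, CONTINUOUS_COVARIATES)
            A = _check_full_rank(X)
            Y = expression.to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
            out = pd.DataFrame(Y - (A @ beta).T, index=expression.index,
                               columns=expression.columns)
        else:
            out = expression.astype(float).copy()

    if scale:
        out = standardize(out)
    return ResidualMatrix(values=out, standardized=bool(scale),
                          platform=platform)
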