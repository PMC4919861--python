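"""Sparse Gaussian graphical model estimation.

A Gaussian graphical model assumes the node vector D ~ N(mu, Sigma); the
precision (concentration) matrix Theta = Sigma^{-1} encodes the network:
theta_ij = 0 iff nodes i and j are conditionally independent given the rest,
and the partial correlation is rho_ij = -theta_ij / sqrt(theta_ii theta_jj).

For p comparable to (or larger than) n a sparse estimate is obtained by
maximising the L1-penalised log-likelihood

    log|Theta| - Trace(S Theta) - lambda * ||Theta||_1,off

over positive-definite matrices, with S the sample covariance matrix.  The
solver below is a primal block coordinate-descent: each node update is an
exact lasso sub-problem on the corresponding row/column of Theta, so the
penalised objective is monotone non-decreasing over sweeps and the iterate
stays positive definite throughout.  By default the diagonal is unpenalised
(the convention of the R package ``huge``); ``penalize_diagonal=True``
reproduces the R ``glasso`` convention.

Penalty selection supports two policies used in comparative designs: a
rotation/permutation null criterion (RIC-style) for the reference network,
and bisection on lambda to match a target edge count so that all networks in
a comparison are of similar size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

#: entries of Theta-hat below this magnitude are treated as structural zeros
ZERO_TOL = 1e-8

#: convergence tolerance on the working covariance, relative to mean |S_ij|
GLASSO_TOL = 1e-7

GLASSO_MAX_SWEEPS = 1000


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CovarianceEstimate:
    """Sample covariance S of a gene-by-sample residual matrix."""

    S: np.ndarray
    n: int
    labels: list[str] = field(default_factory=list)


@dataclass
class PrecisionEstimate:
    """Estimated precision matrix with the penalty that produced it."""

    theta: np.ndarray
    lam: float
    objective: float
    converged: bool
    objective_path: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        t = np.triu(np.abs(self.theta), 1)
        return int(np.count_nonzero(t > ZERO_TOL))


# ---------------------------------------------------------------------------
# sample covariance
# ---------------------------------------------------------------------------

def sample_covariance(residuals) -> CovarianceEstimate:
    """Unbiased (n-1 denominator) covariance across samples.

    ``residuals`` is a ResidualMatrix, a pandas DataFrame or a 2-d array with
    genes as rows and samples as columns.  For standardised residuals S is
    the sample correlation matrix.
    """
    values, labels = _as_matrix(residuals)
    n = values.shape[1]
    if n < 2:
        raise ValueError("at least 2 samples are required for a covariance")
    S = np.cov(values, ddof=1)
    S = np.atleast_2d(S)
    return CovarianceEstimate(S=S, n=n, labels=labels)


def _as_matrix(residuals) -> tuple[np.ndarray, list[str]]:
    if hasattr(residuals, "values") and hasattr(residuals, "standardized"):
        df = residuals.values  # ResidualMatrix
        return df.to_numpy(dtype=float), [str(g) for g in df.index]
    if hasattr(residuals, "to_numpy"):
        return residuals.to_numpy(dtype=float), [str(g) for g in residuals.index]
    arr = np.asarray(residuals, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[0])]


# ---------------------------------------------------------------------------
# numba core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _penalised_objective(S, Theta, lam, pen_diag):
    p = S.shape[0]
    L = np.linalg.cholesky(Theta)
    logdet = 0.0
    for i in range(p):
        logdet += 2.0 * np.log(L[i, i])
    tr = 0.0
    pen = 0.0
    for i in range(p):
        for j in range(p):
            tr += S[i, j] * Theta[j, i]
            if i != j:
                pen += abs(Theta[i, j])
    if pen_diag:
        for i in range(p):
            pen += Theta[i, i]
    return logdet - tr - lam * pen


@njit(cache=True)
def _glasso_core(S, lam, pen_diag, tol, max_sweeps, inner_tol, inner_max):
    """Primal block coordinate descent for the penalised likelihood.

    Each node j update minimises, over the off-diagonal block theta_12 of
    row/column j,

        0.5 * theta_12' (s22 * Theta11^{-1}) theta_12 + s12' theta_12
            + lam * ||theta_12||_1

    (an ordinary lasso), then sets theta_22 = q + 1/s22 with
    q = theta_12' Theta11^{-1} theta_12, which is the exact block minimiser
    and keeps Theta positive definite.
    """
    p = S.shape[0]
    Theta = np.zeros((p, p))
    for i in range(p):
        d = S[i, i] + lam if pen_diag else S[i, i]
        Theta[i, i] = 1.0 / d

    off_mean = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_mean += abs(S[i, j])
                cnt += 1
    if cnt > 0:
        off_mean /= cnt
    if off_mean <= 0.0:
        off_mean = 1.0

    W_old = np.linalg.inv(Theta)
    objs = np.empty(max_sweeps)
    converged = False
    n_sweeps = 0
    idx = np.empty(p - 1, np.int64)
    Theta11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    beta = np.empty(p - 1)

    for sweep in range(max_sweeps):
        for j in range(p):
            k = 0
            for i in range(p):
                if i != j:
                    idx[k] = i
                    k += 1
            for a in range(p - 1):
                s12[a] = S[idx[a], j]
                beta[a] = Theta[idx[a], j]
                for b in range(p - 1):
                    Theta11[a, b] = Theta[idx[a], idx[b]]
            B = np.linalg.inv(Theta11)
            s22 = S[j, j] + lam if pen_diag else S[j, j]
            A = s22 * B

            # warm-started lasso coordinate descent
            for _ in range(inner_max):
                maxd = 0.0
                maxb = 0.0
                for a in range(p - 1):
                    g = s12[a]
                    for b in range(p - 1):
                        if b != a:
                            g += A[a, b] * beta[b]
                    z = -g
                    if z > lam:
                        bn = (z - lam) / A[a, a]
                    elif z < -lam:
                        bn = (z + lam) / A[a, a]
                    else:
                        bn = 0.0
                    d = abs(bn - beta[a])
                    if d > maxd:
                        maxd = d
                    if abs(bn) > maxb:
                        maxb = abs(bn)
                    beta[a] = bn
                if maxd <= inner_tol * (1.0 + maxb):
                    break

            q = 0.0
            for a in range(p - 1):
                for b in range(p - 1):
                    q += beta[a] * B[a, b] * beta[b]
            for a in range(p - 1):
                Theta[idx[a], j] = beta[a]
                Theta[j, idx[a]] = beta[a]
            Theta[j, j] = q + 1.0 / s22

        objs[sweep] = _penalised_objective(S, Theta, lam, pen_diag)
        n_sweeps = sweep + 1
        W = np.linalg.inv(Theta)
        delta = 0.0
        for i in range(p):
            for j in range(p):
                d = abs(W[i, j] - W_old[i, j])
                if d > delta:
                    delta = d
        W_old = W
        if delta < tol * off_mean:
            converged = True
            break

    return Theta, objs[:n_sweeps], converged


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def glasso_fit(
    S,
    lam: float,
    *,
    penalize_diagonal: bool = False,
    tol: float = GLASSO_TOL,
    max_sweeps: int = GLASSO_MAX_SWEEPS,
    labels: list[str] | None = None,
) -> PrecisionEstimate:
    """Maximise log|Theta| - Tr(S Theta) - lam * penalty by coordinate descent.

    Parameters
    ----------
    S : array or CovarianceEstimate
        Symmetric sample covariance (correlation matrix for standardised
        residuals).
    lam : float
        Non-negative L1 penalty.  ``lam=0`` requires an invertible S and
        returns the unpenalised MLE S^{-1}.
    penalize_diagonal : bool
        If False (default, the ``huge`` convention) only off-diagonal entries
        are penalised and the fitted conditional variances satisfy the
        unpenalised stationarity condition; if True the diagonal is penalised
        as in the R ``glasso`` package.
    """
    if isinstance(S, CovarianceEstimate):
        if labels is None:
            labels = S.labels
        S = S.S
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be a square matrix")
    if np.max(np.abs(S - S.T)) > 1e-8:
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    p = S.shape[0]
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have a strictly positive diagonal")
    if lam == 0.0:
        if np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError(
                "lam=0 requires an invertible sample covariance"
            )
    S = np.ascontiguousarray(0.5 * (S + S.T))
    theta, objs, converged = _glasso_core(
        S, float(lam), penalize_diagonal, tol, max_sweeps, 1e-10, 10000
    )
    if not converged:
        warnings.warn(
            f"graphical lasso did not converge in {max_sweeps} sweeps "
            f"(lam={lam:g}, p={p})",
            RuntimeWarning,
        )
    if labels is None:
        labels = [f"g{i}" for i in range(p)]
    return PrecisionEstimate(
        theta=theta,
        lam=float(lam),
        objective=float(objs[-1]),
        converged=bool(converged),
        objective_path=objs,
        labels=list(labels),
    )


def partial_correlations(theta) -> np.ndarray:
    """Partial correlation matrix rho_ij = -theta_ij / sqrt(theta_ii theta_jj).

    The diagonal is reported as 1 by convention.
    """
    if isinstance(theta, PrecisionEstimate):
        theta = theta.theta
    theta = np.asarray(theta, dtype=float)
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have a positive diagonal")
    scale = np.sqrt(d)
    rho = -theta / np.outer(scale, scale)
    np.fill_diagonal(rho, 1.0)
    return rho


def extract_network(theta, labels: list[str] | None = None,
                    zero_tol: float = ZERO_TOL) -> nx.Graph:
    """Zero-structure network: edge (i, j) iff |theta_ij| > zero_tol.

    Edge weights are the partial correlations.  Returns an undirected simple
    graph whose node set is the full label set (isolated nodes included).
    """
    if isinstance(theta, PrecisionEstimate):
        if labels is None:
            labels = theta.labels
        theta = theta.theta
    theta = np.asarray(theta, dtype=float)
    if np.max(np.abs(theta - theta.T)) > 1e-8:
        raise ValueError("precision matrix must be symmetric")
    p = theta.shape[0]
    if labels is None:
        labels = [f"g{i}" for i in range(p)]
    rho = partial_correlations(theta)
    G = nx.Graph()
    G.add_nodes_from(labels)
    ii, jj = np.triu_indices(p, 1)
    mask = np.abs(theta[ii, jj]) > zero_tol
    for i, j in zip(ii[mask], jj[mask]):
        G.add_edge(labels[i], labels[j], weight=float(rho[i, j]))
    return G


def _edge_count(theta: np.ndarray, zero_tol: float = ZERO_TOL) -> int:
    t = np.triu(np.abs(theta), 1)
    return int(np.count_nonzero(t > zero_tol))


def select_lambda_target_edges(
    residuals,
    target_edges: int,
    tolerance: int = 2,
    *,
    penalize_diagonal: bool = False,
    max_steps: int = 50,
    search_tol: float = 1e-5,
) -> float:
    """Bisection on lambda so the fitted network has ~``target_edges`` edges.

    Used to match network sizes across a comparative study.  The edge count
    is non-increasing in lambda along the regularisation path, so bisection
    over [lam_min, max off-diagonal |S|] finds a penalty whose count lands
    within ``tolerance`` of the target; if no penalty attains it within
    ``max_steps`` the closest lambda found is returned with a warning.
    """
    cov = residuals if isinstance(residuals, CovarianceEstimate) \
        else sample_covariance(residuals)
    S = cov.S
    p = S.shape[0]
    max_edges = p * (p - 1) // 2
    if not 0 <= target_edges <= max_edges:
        raise ValueError(f"target_edges must be in [0, {max_edges}]")
    off = np.abs(S - np.diag(np.diag(S)))
    hi = float(off.max())
    if hi == 0.0:
        return 0.0
    if target_edges == 0:
        return hi
    lo = hi * 1e-4

    def count(lam: float) -> int:
        fit = glasso_fit(S, lam, penalize_diagonal=penalize_diagonal,
                         tol=search_tol)
        return _edge_count(fit.theta)

    best_lam, best_gap = hi, abs(0 - target_edges)
    c_lo = count(lo)
    if abs(c_lo - target_edges) < best_gap:
        best_lam, best_gap = lo, abs(c_lo - target_edges)
    if c_lo < target_edges:
        logger.warning(
            "target of %d edges unattainable even at lam=%g (got %d)",
            target_edges, lo, c_lo,
        )
    for _ in range(max_steps):
        mid = np.sqrt(lo * hi)  # geometric bisection on the penalty scale
        c = count(mid)
        gap = abs(c - target_edges)
        if gap < best_gap:
            best_lam, best_gap = mid, gap
        if gap <= tolerance:
            logger.info("lambda=%g achieves %d edges (target %d)", mid, c,
                        target_edges)
            return float(mid)
        if c > target_edges:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-4:
            break
    warnings.warn(
        f"edge target {target_edges} not reached within tolerance "
        f"{tolerance}; returning closest lambda {best_lam:g} "
        f"(gap {best_gap})",
        RuntimeWarning,
    )
    return float(best_lam)


def select_lambda_ric(residuals, n_rotations: int = 20, seed: int = 0) -> float:
    """Permutation-null penalty choice (rotation information criterion style).

    Each replicate permutes every gene's sample order independently, which
    destroys all inter-gene dependence while preserving marginals; the
    largest absolute off-diagonal sample correlation of the permuted data is
    the smallest penalty that would leave the null network empty.  The
    returned lambda is the mean of these maxima over replicates.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    values, _ = _as_matrix(residuals)
    p, n = values.shape
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_rotations)
    for r in range(n_rotations):
        perm = np.empty_like(values)
        for i in range(p):
            perm[i] = values[i, rng.permutation(n)]
        C = np.corrcoef(perm)
        np.fill_diagonal(C, 0.0)
        maxima[r] = np.abs(C).max()
    return float(maxima.mean())
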