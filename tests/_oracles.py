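"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: generic numeric optimisation, dense linear
algebra, brute-force enumeration or simulation.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def penalised_objective(S, theta, lam, penalize_diagonal=False) -> float:
    """log|Theta| - Tr(S Theta) - lam * L1 (off-diagonal counted per entry,
    i.e. each unordered pair twice, matching a full-matrix norm)."""
    sgn, ld = np.linalg.slogdet(theta)
    if sgn <= 0:
        return -np.inf
    pen = np.abs(theta).sum()
    if not penalize_diagonal:
        pen -= np.abs(np.diag(theta)).sum()
    return float(ld - np.trace(S @ theta) - lam * pen)


def glasso_generic_optimizer(S, lam, penalize_diagonal=False) -> np.ndarray:
    """Generic PD-constrained maximiser of the penalised likelihood.

    Parameterises the off-diagonal entries as differences of non-negative
    variables (making the L1 term smooth-with-bounds) and runs L-BFGS-B;
    infeasible (non-PD) iterates are rejected by a large penalty.  This is
    a wholly different algorithm family from coordinate descent.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    k = len(iu[0])

    def unpack(x):
        d, plus, minus = x[:p], x[p:p + k], x[p + k:]
        T = np.zeros((p, p))
        T[iu] = plus - minus
        T += T.T
        T[np.diag_indices(p)] = d
        return T

    def fun(x):
        T = unpack(x)
        sgn, ld = np.linalg.slogdet(T)
        if sgn <= 0 or not np.isfinite(ld):
            return 1e10, np.zeros_like(x)
        Ti = np.linalg.inv(T)
        G = S - Ti  # gradient of the smooth part of the *negated* objective
        gd = np.diag(G) + (lam if penalize_diagonal else 0.0)
        goff = 2.0 * G[iu]
        grad = np.concatenate([gd, goff + 2.0 * lam, -goff + 2.0 * lam])
        pen = lam * (2.0 * x[p:].sum()
                     + (np.abs(x[:p]).sum() if penalize_diagonal else 0.0))
        return -(ld - np.trace(S @ T)) + pen, grad

    x0 = np.concatenate([1.0 / np.diag(S), np.zeros(2 * k)])
    bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * k)
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=20000, maxfun=100000, ftol=1e-16, gtol=1e-12))
    return unpack(res.x)


def partial_corr_by_inversion(theta) -> np.ndarray:
    """Partial correlations recomputed via Sigma = Theta^{-1} -> Theta:
    an independent dense-inversion route."""
    sigma = np.linalg.inv(np.asarray(theta, dtype=float))
    t = np.linalg.inv(sigma)
    d = np.sqrt(np.diag(t))
    rho = -t / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def sample_partial_correlation(x, y, z) -> float:
    """Partial correlation of x and y given z via residualised Pearson."""
    z = np.column_stack([np.ones_like(z), z])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def covariance_double_loop(values) -> np.ndarray:
    """Brute-force n-1 denominator covariance."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    means = values.mean(axis=1)
    S = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            S[i, j] = np.sum(
                (values[i] - means[i]) * (values[j] - means[j])) / (n - 1)
    return S


def poisson_loglik_optimizer(y, X, offset) -> np.ndarray:
    """Maximise the Poisson log-likelihood with a generic optimiser."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def nll(beta):
        eta = X @ beta + offset
        return float(np.sum(np.exp(eta) - y * eta))

    def grad(beta):
        mu = np.exp(X @ beta + offset)
        return X.T @ (mu - y)

    x0 = np.zeros(X.shape[1])
    res = optimize.minimize(nll, x0, jac=grad, method="BFGS",
                            options=dict(maxiter=5000, gtol=1e-10))
    return res.x


def ols_normal_equations(y, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))


def hypergeom_tail_bruteforce(o, N, K, n) -> float:
    """P(X >= o) for X ~ Hypergeom(N, K, n) via explicit binomial sums."""
    from math import comb
    denom = comb(N, n)
    total = 0
    for k in range(o, min(K, n) + 1):
        if n - k <= N - K:
            total += comb(K, k) * comb(N - K, n - k)
    return total / denom
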