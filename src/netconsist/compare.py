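"""Agreement between inferred networks: graph correlation, QAP permutation
tests, bootstrap confidence intervals, differential networks and
node-variance diagnostics.

Agreement between two networks on the same node set is the product-moment
(Pearson) correlation between their 0/1 adjacency indicators over the
p(p-1)/2 unordered node pairs.  Its significance is assessed with a QAP
(quadratic assignment procedure) test: node labels of one graph are
permuted uniformly at random and the correlation recomputed, giving an
exact-style one-sided p-value (1 + #{perm >= obs}) / (n_perm + 1).

The two-step regress-then-infer procedure understates uncertainty, so
confidence intervals for graph correlations are obtained by non-parametric
bootstrap: samples (columns) are resampled with replacement, the full
analysis — regression, penalty matching, network extraction — is rerun per
replicate, and percentile intervals are reported (typically asymmetric).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ggm import extract_network, glasso_fit, sample_covariance, \
    select_lambda_target_edges
from .regression import residual_pipeline

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    label_a: str
    label_b: str
    correlation: float
    qap_pvalue: float | None = None
    n_permutations: int = 0
    ci: tuple[float, float] | None = None
    replicates: np.ndarray | None = None
    n_dropped: int = 0
    resample_signature: str | None = None


# ---------------------------------------------------------------------------
# adjacency vectorisation and graph correlation
# ---------------------------------------------------------------------------

def _aligned_nodes(A: nx.Graph, B: nx.Graph) -> list:
    na, nb = set(A.nodes), set(B.nodes)
    if na != nb:
        raise ValueError("networks are defined on different node sets")
    return sorted(na, key=str)


def _dyad_vector(G: nx.Graph, nodes: list) -> np.ndarray:
    idx = {v: i for i, v in enumerate(nodes)}
    p = len(nodes)
    M = np.zeros((p, p), dtype=float)
    for a, b in G.edges:
        i, j = idx[a], idx[b]
        if i != j:
            M[i, j] = M[j, i] = 1.0
    iu = np.triu_indices(p, 1)
    return M[iu]


def graph_correlation(A: nx.Graph, B: nx.Graph) -> float:
    """Pearson correlation of the adjacency indicators over unordered dyads."""
    nodes = _aligned_nodes(A, B)
    va, vb = _dyad_vector(A, nodes), _dyad_vector(B, nodes)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError(
            "graph correlation undefined for empty or complete graphs"
        )
    return float(np.corrcoef(va, vb)[0, 1])


def qap_test(
    A: nx.Graph,
    B: nx.Graph,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> float:
    """One-sided (greater) QAP p-value for the graph correlation of A and B.

    ``exact=True`` enumerates all node permutations (only feasible for tiny
    graphs) and returns #{perm >= obs} / p!.
    """
    nodes = _aligned_nodes(A, B)
    p = len(nodes)
    va = _dyad_vector(A, nodes)
    Mb = np.zeros((p, p))
    idx = {v: i for i, v in enumerate(nodes)}
    for a, b in B.edges:
        i, j = idx[a], idx[b]
        Mb[i, j] = Mb[j, i] = 1.0
    iu = np.triu_indices(p, 1)
    vb = Mb[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("QAP test undefined for empty or complete graphs")
    obs = np.corrcoef(va, vb)[0, 1]

    if exact:
        from itertools import permutations
        total = 0
        ge = 0
        for perm in permutations(range(p)):
            perm = np.asarray(perm)
            vperm = Mb[np.ix_(perm, perm)][iu]
            total += 1
            if np.corrcoef(va, vperm)[0, 1] >= obs - 1e-12:
                ge += 1
        return ge / total

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(p)
        vperm = Mb[np.ix_(perm, perm)][iu]
        if np.corrcoef(va, vperm)[0, 1] >= obs - 1e-12:
            ge += 1
    return (1 + ge) / (n_perm + 1)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _one_network(expression: pd.DataFrame, covariates: pd.DataFrame,
                 platform: str, target_edges: int, *, scale: bool,
                 correct_confounders: bool, penalize_diagonal: bool,
                 lam: float | None = None) -> nx.Graph:
    res = residual_pipeline(expression, covariates, platform, scale=scale,
                            correct_confounders=correct_confounders)
    cov = sample_covariance(res)
    if lam is None:
        lam = select_lambda_target_edges(
            cov, target_edges, penalize_diagonal=penalize_diagonal)
    fit = glasso_fit(cov, lam, penalize_diagonal=penalize_diagonal,
                     labels=cov.labels)
    return extract_network(fit)


def bootstrap_consistency(
    expr_a: pd.DataFrame,
    cov_a: pd.DataFrame,
    platform_a: str,
    expr_b: pd.DataFrame,
    cov_b: pd.DataFrame,
    platform_b: str,
    *,
    target_edges: int,
    n_boot: int = 100,
    seed: int = 0,
    scale: bool = True,
    correct_confounders: bool = True,
    penalize_diagonal: bool = False,
    scale_b: bool | None = None,
    correct_confounders_b: bool | None = None,
    label_a: str = "A",
    label_b: str = "B",
    share_resamples: bool | None = None,
) -> ComparisonResult:
    """Bootstrap CI for the graph correlation between two datasets' networks.

    Samples (columns) are resampled with replacement independently within
    each dataset; the full two-step analysis, including re-selection of
    lambda to the target edge count, is rerun per replicate.  Replicates
    that fail (e.g. a resampled gene becomes constant) are dropped with a
    warning; more than 20 % dropped is an error.  The resample index stream
    depends only on ``seed``, so two calls with the same seed and sample
    sizes are paired replicate-by-replicate.

    When the two inputs are the same dataset analysed twice (e.g. two
    analysis arms on one cohort), set ``share_resamples=True`` so each
    replicate draws one resample applied to both sides; by default this is
    detected automatically when the data frames are equal.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if scale_b is None:
        scale_b = scale
    if correct_confounders_b is None:
        correct_confounders_b = correct_confounders
    if share_resamples is None:
        share_resamples = (expr_a.shape == expr_b.shape
                           and expr_a.equals(expr_b)
                           and cov_a.equals(cov_b))
    point_net_a = _one_network(expr_a, cov_a, platform_a, target_edges,
                               scale=scale,
                               correct_confounders=correct_confounders,
                               penalize_diagonal=penalize_diagonal)
    point_net_b = _one_network(expr_b, cov_b, platform_b, target_edges,
                               scale=scale_b,
                               correct_confounders=correct_confounders_b,
                               penalize_diagonal=penalize_diagonal)
    point = graph_correlation(point_net_a, point_net_b)

    rng = np.random.default_rng(seed)
    n_a, n_b = expr_a.shape[1], expr_b.shape[1]
    idx_a = rng.integers(0, n_a, size=(n_boot, n_a))
    if share_resamples:
        if n_a != n_b:
            raise ValueError("share_resamples requires equal sample sizes")
        idx_b = idx_a
    else:
        idx_b = rng.integers(0, n_b, size=(n_boot, n_b))
    signature = hashlib.sha256(
        idx_a.tobytes() + idx_b.tobytes()).hexdigest()[:16]

    reps = []
    dropped = 0
    for b in range(n_boot):
        try:
            ea = _resample(expr_a, cov_a, idx_a[b])
            eb = _resample(expr_b, cov_b, idx_b[b])
            net_a = _one_network(ea[0], ea[1], platform_a, target_edges,
                                 scale=scale,
                                 correct_confounders=correct_confounders,
                                 penalize_diagonal=penalize_diagonal)
            net_b = _one_network(eb[0], eb[1], platform_b, target_edges,
                                 scale=scale_b,
                                 correct_confounders=correct_confounders_b,
                                 penalize_diagonal=penalize_diagonal)
            reps.append(graph_correlation(net_a, net_b))
        except (ValueError, np.linalg.LinAlgError) as exc:
            dropped += 1
            reps.append(np.nan)
            warnings.warn(f"bootstrap replicate {b} dropped: {exc}",
                          RuntimeWarning)
    if dropped > 0.2 * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap replicates failed"
        )
    reps = np.asarray(reps)
    good = reps[~np.isnan(reps)]
    ci = (float(np.percentile(good, 2.5)), float(np.percentile(good, 97.5)))
    return ComparisonResult(
        label_a=label_a, label_b=label_b, correlation=float(point),
        ci=ci, replicates=reps, n_dropped=dropped,
        resample_signature=signature,
    )


def _resample(expr: pd.DataFrame, cov: pd.DataFrame, idx: np.ndarray):
    cols = expr.columns[idx]
    e = expr.iloc[:, idx].copy()
    c = cov.loc[cols].copy()
    new_ids = [f"b{k:04d}" for k in range(len(idx))]
    e.columns = new_ids
    c.index = pd.Index(new_ids, name="sample_id")
    return e, c


def compare_correlations(result_a: ComparisonResult,
                         result_b: ComparisonResult) -> float:
    """One-sided paired-bootstrap p-value for corr(A) > corr(B).

    Both results must carry replicate values computed on a common resample
    stream (same seed and sample sizes); the p-value is the proportion of
    paired replicates where the difference is <= 0, with the +1/(B+1)
    correction.
    """
    ra, rb = result_a.replicates, result_b.replicates
    if ra is None or rb is None or len(ra) != len(rb):
        raise ValueError("results do not carry paired bootstrap replicates")
    if (result_a.resample_signature is None
            or result_a.resample_signature != result_b.resample_signature):
        raise ValueError("bootstrap replicates were not drawn from common "
                         "resamples; rerun both analyses with the same seed")
    ok = ~(np.isnan(ra) | np.isnan(rb))
    diff = ra[ok] - rb[ok]
    B = diff.size
    return float((1 + np.sum(diff <= 0)) / (B + 1))


# ---------------------------------------------------------------------------
# differential networks and set operations
# ---------------------------------------------------------------------------

def differential_network(A: nx.Graph, B: nx.Graph) -> nx.Graph:
    """Edges present in A but not in B, on the common node set."""
    nodes = _aligned_nodes(A, B)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for a, b in A.edges:
        if not B.has_edge(a, b):
            G.add_edge(a, b, **A.edges[a, b])
    return G


def multi_network_intersection(*networks: nx.Graph) -> nx.Graph:
    """Edges present in every input network (>= 2, same node sets)."""
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    nodes = _aligned_nodes(networks[0], networks[1])
    for other in networks[2:]:
        _aligned_nodes(networks[0], other)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for a, b in networks[0].edges:
        if all(N.has_edge(a, b) for N in networks[1:]):
            G.add_edge(a, b, **networks[0].edges[a, b])
    return G


# ---------------------------------------------------------------------------
# node-variance diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DegreeVarianceProfile:
    table: pd.DataFrame
    spearman: float
    pearson: float
    degenerate: bool = False


def degree_variance_profile(network: nx.Graph,
                            node_variances) -> DegreeVarianceProfile:
    """Per-node degree vs. variance, with log-log rank/linear correlations.

    Quantifies how strongly the connectivity of a node is coupled to its
    variance (the hallmark of network inference on unscaled data).  Degrees
    enter as log(1 + degree) so isolated nodes are defined.
    """
    nv = pd.Series(node_variances)
    if (nv <= 0).any():
        raise ValueError("node variances must be positive")
    nodes = sorted(network.nodes, key=str)
    if set(nodes) - set(nv.index):
        raise ValueError("variances missing for some network nodes")
    deg = np.array([network.degree(v) for v in nodes], dtype=float)
    var = nv.loc[nodes].to_numpy(dtype=float)
    table = pd.DataFrame({
        "node": nodes,
        "degree": deg.astype(int),
        "variance": var,
        "log_degree": np.log1p(deg),
        "log_variance": np.log(var),
    })
    if np.ptp(deg) == 0 or np.ptp(var) == 0:
        return DegreeVarianceProfile(table, 0.0, 0.0, degenerate=True)
    sp = stats.spearmanr(table["log_degree"], table["log_variance"]).statistic
    pe = stats.pearsonr(table["log_degree"], table["log_variance"]).statistic
    return DegreeVarianceProfile(table, float(sp), float(pe))


@dataclass
class DegreeDistribution:
    counts: pd.Series  # index: degree, value: number of nodes
    max_degree: int
    gini: float


def degree_gini(degrees: np.ndarray) -> float:
    """Gini coefficient of the degree sequence (tail-heaviness index)."""
    d = np.sort(np.asarray(degrees, dtype=float))
    n = d.size
    if n == 0 or d.sum() == 0:
        return 0.0
    cum = np.cumsum(d)
    return float((n + 1 - 2 * np.sum(cum) / cum[-1]) / n)


def degree_distribution(network: nx.Graph) -> DegreeDistribution:
    degrees = np.array([d for _, d in network.degree], dtype=int)
    if degrees.size == 0:
        return DegreeDistribution(pd.Series(dtype=int), 0, 0.0)
    counts = pd.Series(degrees).value_counts().sort_index()
    counts.index.name = "degree"
    return DegreeDistribution(counts=counts,
                              max_degree=int(degrees.max()),
                              gini=degree_gini(degrees))
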