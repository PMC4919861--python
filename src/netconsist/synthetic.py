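"""Paired two-platform expression data with a known latent network.

The generator emulates the statistical structure that the downstream
two-step analysis assumes: a shared sparse latent precision matrix Theta
drives both a sequencing-like count platform and a microarray-like
continuous platform, with

* per-sample confounder effects on expression (age, sex, BMI, glucose,
  smoking, plus technical GC content and library size for counts),
* platform-specific per-gene scale multipliers s_i — node variances are
  deliberately *not* consistent across the two platforms,
* library-size variation for counts, entering as a Poisson offset.

Latent values Z (gene x sample, columns iid N(0, Theta^{-1})) enter the
count platform through the log link,

    Y_ij ~ Poisson(lambda_ij),
    log lambda_ij = log n_j + x_j' beta_i + s_i Z_ij,

so the marginal count variance scales with the mean, and the continuous
platform linearly,

    M_ij = alpha_i + x_j' beta_i + s_i Z_ij + eps_ij.

All draws are bit-reproducible from the scenario seed; stage seeds are
derived with numpy's SeedSequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as ncio
from .ggm import extract_network, partial_correlations

#: per-covariate standard deviation of the per-gene confounder coefficients,
#: log scale for counts
DEFAULT_EFFECTS_COUNT = {
    "age": 0.004, "sex": 0.15, "bmi": 0.01,
    "glucose": 0.05, "smoking": 0.10, "gc": 2.0,
}
#: continuous platform, expression units
DEFAULT_EFFECTS_CONTINUOUS = {
    "age": 0.010, "sex": 0.40, "bmi": 0.03,
    "glucose": 0.12, "smoking": 0.30,
}

_LOG_LAMBDA_CAP = 30.0


@dataclass
class SyntheticScenario:
    """Full generative parameterisation of a paired-platform study."""

    p: int = 30
    n: int = 100
    topology: str = "random"  # chain | random | hub
    partial_corr_strength: float = 0.3
    seed: int = 0
    # topology knobs
    density: float | None = None  # random topology; default 2/p
    n_hubs: int = 2
    hub_degree: int | None = None
    edge_sign: str = "positive"  # or "mixed"
    # platform node scales (explicit vectors override log-uniform ranges)
    node_scale_range_count: tuple[float, float] = (0.1, 0.6)
    node_scale_range_continuous: tuple[float, float] = (1.0, 6.0)
    node_scales_count: list[float] | None = None
    node_scales_continuous: list[float] | None = None
    # confounders
    confounder_effects_count: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS_COUNT))
    confounder_effects_continuous: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS_CONTINUOUS))
    # count platform
    library_size_range: tuple[float, float] = (50_000, 200_000)
    baseline_log_abundance_sd: float = 0.7
    # continuous platform
    continuous_baseline_mean: float = 7.0
    continuous_baseline_sd: float = 1.0
    noise_sd_continuous: float = 0.3
    # groups / differential structure
    group_fraction_high: float = 0.5
    n_group_edges: int = 0  # true edges present only in the high-glucose group

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ValueError("p must be >= 3")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.partial_corr_strength < 1.0:
            raise ValueError("partial_corr_strength must be in (0, 1)")
        if self.topology not in ("chain", "random", "hub"):
            raise ValueError("topology must be chain, random or hub")
        lo, hi = self.library_size_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("library sizes must be positive with min <= max")
        for v in (self.node_scales_count, self.node_scales_continuous):
            if v is not None and (len(v) != self.p or min(v) <= 0):
                raise ValueError("explicit node scales must be p positive values")

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic sub-seeds (< 2**31) for each generation stage."""
        names = ["precision", "latent", "covariates", "counts", "continuous",
                 "effects_count", "effects_continuous", "scales",
                 "group_edges", "latent_high"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {k: int(s & 0x7FFFFFFF) for k, s in zip(names, state)}


@dataclass
class SyntheticData:
    """Realised datasets plus the ground truth that generated them."""

    scenario: SyntheticScenario
    theta: np.ndarray
    network_true: nx.Graph
    z: np.ndarray
    covariates: pd.DataFrame
    counts: pd.DataFrame
    continuous: pd.DataFrame
    gene_ids: list[str]
    node_scales_count: np.ndarray
    node_scales_continuous: np.ndarray
    theta_high: np.ndarray | None = None
    network_true_high: nx.Graph | None = None
    group_specific_edges: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ground-truth precision matrix
# ---------------------------------------------------------------------------

def _topology_edges(p: int, topology: str, rng: np.random.Generator,
                    density: float | None, n_hubs: int,
                    hub_degree: int | None) -> list[tuple[int, int]]:
    if topology == "chain":
        return [(i, i + 1) for i in range(p - 1)]
    if topology == "random":
        d = 2.0 / p if density is None else density
        edges = []
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < d:
                    edges.append((i, j))
        return edges
    # hub: a few high-degree nodes wired to distinct leaves
    deg = hub_degree if hub_degree is not None else min(p - 1, max(4, p // 4))
    hubs = list(range(n_hubs))
    others = np.array([i for i in range(p) if i not in hubs])
    edges = []
    for h in hubs:
        picks = rng.choice(others, size=min(deg, others.size), replace=False)
        edges.extend((min(h, int(o)), max(h, int(o))) for o in picks)
    return sorted(set(edges))


def _build_precision(p: int, edges: list[tuple[int, int]], strength: float,
                     signs: np.ndarray, inflation: float) -> np.ndarray:
    """Theta = (1 + inflation) I - strength * A_signed.

    With unit (conditional-variance) diagonal, theta_ij = -sign * strength
    gives partial correlation rho_ij = sign * strength / (1 + inflation) on
    every edge — exactly ``strength`` when no inflation is needed.  Positive
    definiteness requires strength * lambda_max(A) < 1 + inflation.
    """
    theta = np.zeros((p, p))
    for k, (i, j) in enumerate(edges):
        theta[i, j] = theta[j, i] = -signs[k] * strength
    np.fill_diagonal(theta, 1.0 + inflation)
    return theta


def make_precision_matrix(
    p: int,
    topology: str,
    strength: float,
    seed: int = 0,
    *,
    density: float | None = None,
    n_hubs: int = 2,
    hub_degree: int | None = None,
    edge_sign: str = "positive",
    edges: list[tuple[int, int]] | None = None,
    max_retries: int = 25,
) -> np.ndarray:
    """Symmetric positive-definite Theta whose support matches ``topology``.

    Conditional variances are set to one, so every true edge has partial
    correlation of magnitude exactly ``strength``; when the support is dense
    enough that this is not positive definite, the diagonal is inflated
    minimally, shrinking the edge partial correlations uniformly.  If the
    shrinkage exceeds 0.05 the construction fails (the requested strength is
    infeasible for that support).  ``edges`` overrides the topology with an
    explicit support (used for planted group differences).
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    if not 0.0 < strength < 1.0:
        raise ValueError("strength must be in (0, 1)")
    rng = np.random.default_rng(seed)
    explicit_support = edges is not None or topology != "random"
    if edges is None:
        edges = _topology_edges(p, topology, rng, density, n_hubs, hub_degree)
    if edge_sign == "mixed":
        signs = rng.choice([-1.0, 1.0], size=len(edges))
    else:
        signs = np.ones(len(edges))
    # eigenvalue floor keeps Theta well-conditioned (the unit-variance
    # congruence below bounds the marginal variances regardless)
    floor = 0.05
    for _ in range(max_retries):
        theta = _build_precision(p, edges, strength, signs, 0.0)
        min_eig = float(np.linalg.eigvalsh(theta)[0])
        inflation = max(0.0, floor - min_eig)
        if inflation > 0.0:
            theta = _build_precision(p, edges, strength, signs, inflation)
        rho = partial_correlations(theta)
        if all(abs(abs(rho[i, j]) - strength) <= 0.05 for i, j in edges):
            # diagonal congruence so Theta^{-1} has unit diagonal: the
            # latent field then has unit marginal variances and the
            # platform scale multipliers alone set the node variances.
            # Support and partial correlations are exactly preserved.
            sigma = np.linalg.inv(theta)
            d = np.sqrt(np.diag(sigma))
            return theta * np.outer(d, d)
        if explicit_support:
            break
        # an ER draw whose spectral radius makes the strength infeasible:
        # redraw the random support
        edges = _topology_edges(p, topology, rng, density, n_hubs, hub_degree)
        if edge_sign == "mixed":
            signs = rng.choice([-1.0, 1.0], size=len(edges))
        else:
            signs = np.ones(len(edges))
    raise RuntimeError(
        f"no positive-definite precision matrix has |partial correlation| "
        f"within 0.05 of {strength} on this support "
        f"(topology={topology}, p={p}, {len(edges)} edges)"
    )


# ---------------------------------------------------------------------------
# latent field and covariates
# ---------------------------------------------------------------------------

def sample_latent(theta: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Gene-by-sample matrix whose columns are iid N(0, Theta^{-1})."""
    theta = np.asarray(theta, dtype=float)
    try:
        np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("theta must be positive definite") from exc
    sigma = np.linalg.inv(theta)
    sigma = 0.5 * (sigma + sigma.T)
    L = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal((theta.shape[0], n))


def generate_covariates(
    n: int,
    seed: int = 0,
    *,
    library_size_range: tuple[float, float] = (50_000, 200_000),
    group_fraction_high: float = 0.5,
    sex_p: float = 0.5,
    smoking_p: float = 0.3,
) -> pd.DataFrame:
    """Per-sample covariate table with plausible marginals.

    Defaults: age ~ U(20, 70) years, sex ~ Bernoulli(0.5), BMI ~ N(25.5,
    3.8^2) kg/m^2 clipped to [16, 45], smoking ~ Bernoulli(0.3), GC content
    ~ N(0.45, 0.02^2).  Samples are split into high / low fasting-glucose
    groups (both always represented); glucose is drawn above 5.9 mmol/l in
    the high group and below 4.8 mmol/l in the low group.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    ids = [f"s{i + 1:04d}" for i in range(n)]
    n_high = int(np.clip(round(n * group_fraction_high), 1, n - 1))
    group = np.array(["low"] * n, dtype=object)
    group[rng.permutation(n)[:n_high]] = "high"
    glucose = np.where(
        group == "high",
        np.maximum(rng.normal(6.5, 0.4, n), 5.9),
        np.minimum(rng.normal(4.4, 0.3, n), 4.8),
    )
    lo, hi = library_size_range
    df = pd.DataFrame(
        {
            "age": rng.uniform(20, 70, n),
            "sex": rng.binomial(1, sex_p, n),
            "bmi": np.clip(rng.normal(25.5, 3.8, n), 16, 45),
            "glucose": glucose,
            "smoking": rng.binomial(1, smoking_p, n),
            "group": group,
            "library_size": rng.integers(int(lo), int(hi) + 1, n),
            "gc": rng.normal(0.45, 0.02, n),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return df


# ---------------------------------------------------------------------------
# platform rendering
# ---------------------------------------------------------------------------

def _draw_scales(scenario: SyntheticScenario, platform: str,
                 rng: np.random.Generator) -> np.ndarray:
    explicit = (scenario.node_scales_count if platform == "counts"
                else scenario.node_scales_continuous)
    if explicit is not None:
        return np.asarray(explicit, dtype=float)
    lo, hi = (scenario.node_scale_range_count if platform == "counts"
              else scenario.node_scale_range_continuous)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), scenario.p))


def _draw_effects(scenario: SyntheticScenario, platform: str,
                  rng: np.random.Generator) -> pd.DataFrame:
    effect_sds = (scenario.confounder_effects_count if platform == "counts"
                  else scenario.confounder_effects_continuous)
    eff = pd.DataFrame(index=range(scenario.p))
    for c, sd in effect_sds.items():
        eff[c] = rng.normal(0.0, sd, scenario.p)
    return eff


def node_scales(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """The per-gene scale multipliers for (counts, continuous)."""
    seeds = scenario.stage_seeds()
    rng = np.random.default_rng(seeds["scales"])
    return (_draw_scales(scenario, "counts", rng),
            _draw_scales(scenario, "continuous", rng))


def render_count_platform(
    z: np.ndarray,
    covariates: pd.DataFrame,
    scenario: SyntheticScenario,
    *,
    seed: int | None = None,
    scales: np.ndarray | None = None,
) -> pd.DataFrame:
    """Poisson counts with library-size offset and confounder effects."""
    p, n = z.shape
    if len(covariates) != n:
        raise ValueError("latent matrix and covariate table sizes differ")
    seeds = scenario.stage_seeds()
    if seed is None:
        seed = seeds["counts"]
    if scales is None:
        scales = node_scales(scenario)[0]
    effects = _draw_effects(scenario, "counts",
                            np.random.default_rng(seeds["effects_count"]))
    rng = np.random.default_rng(seed)
    alpha = np.log(1.0 / p) + rng.normal(
        0.0, scenario.baseline_log_abundance_sd, p)
    X = covariates[list(effects.columns)].to_numpy(dtype=float)
    lib = covariates["library_size"].to_numpy(dtype=float)
    log_lam = (np.log(lib)[None, :] + alpha[:, None]
               + effects.to_numpy() @ X.T + scales[:, None] * z)
    if np.any(log_lam > _LOG_LAMBDA_CAP):
        warnings.warn("Poisson log-mean capped to avoid overflow",
                      RuntimeWarning)
        log_lam = np.minimum(log_lam, _LOG_LAMBDA_CAP)
    counts = rng.poisson(np.exp(log_lam))
    return pd.DataFrame(counts,
                        index=pd.Index(_gene_ids(p), name="gene_id"),
                        columns=covariates.index)


def render_continuous_platform(
    z: np.ndarray,
    covariates: pd.DataFrame,
    scenario: SyntheticScenario,
    *,
    seed: int | None = None,
    scales: np.ndarray | None = None,
) -> pd.DataFrame:
    """Continuous expression: baseline + confounders + scaled latent + noise."""
    p, n = z.shape
    if len(covariates) != n:
        raise ValueError("latent matrix and covariate table sizes differ")
    seeds = scenario.stage_seeds()
    if seed is None:
        seed = seeds["continuous"]
    if scales is None:
        scales = node_scales(scenario)[1]
    effects = _draw_effects(scenario, "continuous",
                            np.random.default_rng(seeds["effects_continuous"]))
    rng = np.random.default_rng(seed)
    alpha = rng.normal(scenario.continuous_baseline_mean,
                       scenario.continuous_baseline_sd, p)
    X = covariates[list(effects.columns)].to_numpy(dtype=float)
    M = (alpha[:, None] + effects.to_numpy() @ X.T + scales[:, None] * z
         + rng.normal(0.0, scenario.noise_sd_continuous, (p, n)))
    return pd.DataFrame(M,
                        index=pd.Index(_gene_ids(p), name="gene_id"),
                        columns=covariates.index)


def _gene_ids(p: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(p)]


# ---------------------------------------------------------------------------
# full scenario realisation
# ---------------------------------------------------------------------------

def simulate(scenario: SyntheticScenario) -> SyntheticData:
    """Generate a complete paired-platform dataset from a scenario."""
    seeds = scenario.stage_seeds()
    theta = make_precision_matrix(
        scenario.p, scenario.topology, scenario.partial_corr_strength,
        seeds["precision"], edge_sign=scenario.edge_sign,
        density=scenario.density, n_hubs=scenario.n_hubs,
        hub_degree=scenario.hub_degree)
    base_edges = [(i, j) for i in range(scenario.p)
                  for j in range(i + 1, scenario.p)
                  if abs(theta[i, j]) > 1e-12]
    gene_ids = _gene_ids(scenario.p)

    covariates = generate_covariates(
        scenario.n, seeds["covariates"],
        library_size_range=scenario.library_size_range,
        group_fraction_high=scenario.group_fraction_high)

    theta_high = None
    group_edges: list[tuple[str, str]] = []
    if scenario.n_group_edges > 0:
        rng_ge = np.random.default_rng(seeds["group_edges"])
        present = set(base_edges)
        candidates = [(i, j) for i in range(scenario.p)
                      for j in range(i + 1, scenario.p)
                      if (i, j) not in present]
        k = min(scenario.n_group_edges, len(candidates))
        for _ in range(20):  # redraw if the augmented support is infeasible
            picks = rng_ge.choice(len(candidates), size=k, replace=False)
            extra = [candidates[int(c)] for c in picks]
            try:
                theta_high = make_precision_matrix(
                    scenario.p, scenario.topology,
                    scenario.partial_corr_strength,
                    seeds["precision"], edge_sign=scenario.edge_sign,
                    edges=sorted(present | set(extra)))
                break
            except RuntimeError:
                continue
        else:
            raise RuntimeError("could not plant group-specific edges")
        group_edges = [tuple(sorted((gene_ids[i], gene_ids[j])))
                       for i, j in extra]

    if theta_high is None:
        z = sample_latent(theta, scenario.n, seeds["latent"])
    else:
        # group-specific latent structure: high-glucose columns follow the
        # augmented precision matrix, low-glucose columns the base one
        high = (covariates["group"] == "high").to_numpy()
        z = np.empty((scenario.p, scenario.n))
        z_low = sample_latent(theta, int((~high).sum()), seeds["latent"])
        z_high = sample_latent(theta_high, int(high.sum()),
                               seeds["latent_high"])
        z[:, ~high] = z_low
        z[:, high] = z_high

    sc_count, sc_cont = node_scales(scenario)
    counts = render_count_platform(z, covariates, scenario, scales=sc_count)
    continuous = render_continuous_platform(z, covariates, scenario,
                                            scales=sc_cont)
    return SyntheticData(
        scenario=scenario,
        theta=theta,
        network_true=extract_network(theta, gene_ids),
        z=z,
        covariates=covariates,
        counts=counts,
        continuous=continuous,
        gene_ids=gene_ids,
        node_scales_count=sc_count,
        node_scales_continuous=sc_cont,
        theta_high=theta_high,
        network_true_high=(None if theta_high is None
                           else extract_network(theta_high, gene_ids)),
        group_specific_edges=group_edges,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    d = asdict(scenario)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def scenario_from_yaml(path) -> SyntheticScenario:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("node_scale_range_count", "node_scale_range_continuous",
              "library_size_range"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return SyntheticScenario(**d)


def write_dataset(data: SyntheticData, outdir) -> None:
    """Expression, covariate, truth and scenario files for one realisation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ncio.write_expression_tsv(data.counts, outdir / "counts.tsv", integer=True)
    ncio.write_expression_tsv(data.continuous, outdir / "continuous.tsv")
    ncio.write_covariates_tsv(data.covariates, outdir / "covariates.tsv")
    ncio.write_network_tsv(data.network_true, outdir / "network_true.tsv")
    if data.network_true_high is not None:
        ncio.write_network_tsv(data.network_true_high,
                               outdir / "network_true_high.tsv")
    scenario_to_yaml(data.scenario, outdir / "scenario.yaml")
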