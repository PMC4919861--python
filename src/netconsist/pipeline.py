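"""End-to-end study pipeline on a synthetic scenario.

Simulates paired count/continuous platforms sharing one latent network,
runs the configured analysis arms (scaled / non-scaled residuals,
confounder-corrected / uncorrected), matches all networks to a common size
via the penalty, and produces the comparison table (graph correlations with
QAP p-values), node-variance diagnostics, pathway-pair enrichment networks
and, when the scenario defines glucose groups, differential networks.

Everything is deterministic given (config, seed); the summary is written as
sorted-key JSON so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import io as ncio
from .compare import (degree_distribution, degree_variance_profile,
                      differential_network, graph_correlation,
                      multi_network_intersection, qap_test)
from .enrichment import (all_pairs_enrichment, enrichment_network,
                         filter_pathways, make_random_gene_sets, pvalue_qq,
                         read_gmt, write_enrichment_tsv, write_gmt)
from .ggm import (extract_network, glasso_fit, sample_covariance,
                  select_lambda_ric, select_lambda_target_edges)
from .regression import residual_pipeline
from .synthetic import SyntheticScenario, simulate, write_dataset

logger = logging.getLogger(__name__)

#: the comparative arms of the design: whether residuals are standardised
#: and whether confounders are regressed out.  The non-scaled arm penalises
#: the diagonal (the convention of the R glasso package, which does not
#: scale data); the scaled arms leave it unpenalised (huge convention).
DEFAULT_ARMS = (
    {"name": "scaled_corrected", "scale": True, "correct_confounders": True,
     "penalize_diagonal": False},
    {"name": "nonscaled_corrected", "scale": False,
     "correct_confounders": True, "penalize_diagonal": True},
    {"name": "scaled_uncorrected", "scale": True,
     "correct_confounders": False, "penalize_diagonal": False},
)

PLATFORMS = ("counts", "continuous")


@dataclass
class PipelineConfig:
    scenario: dict = field(default_factory=dict)
    arms: tuple = DEFAULT_ARMS
    lambda_policy: str = "ric"  # "ric" | "target"
    target_edges: int | None = None
    edge_match_tolerance: int = 2
    ric_rotations: int = 20
    qap_permutations: int = 199
    alpha: float = 0.10
    min_pathway_genes: int = 5
    gene_sets: str | None = None  # GMT path; None -> synthetic random sets
    n_random_sets: int = 10
    run_groups: bool = False
    min_group_samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("at least one analysis arm is required")
        if self.lambda_policy not in ("ric", "target"):
            raise ValueError("lambda_policy must be 'ric' or 'target'")
        if self.lambda_policy == "target" and self.target_edges is None:
            raise ValueError("target policy requires target_edges")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(**raw)


def _scenario_from_config(config: PipelineConfig) -> SyntheticScenario:
    params = dict(config.scenario)
    params.setdefault("seed", config.seed)
    return SyntheticScenario(**params)


def _network_label(arm_name: str, platform: str) -> str:
    return f"{platform}:{arm_name}"


def _fit_arm(expression, covariates, platform, arm, lam=None,
             target_edges=None, tolerance=2):
    """Residuals -> covariance -> penalty -> precision -> network."""
    res = residual_pipeline(
        expression, covariates, platform,
        scale=arm["scale"],
        correct_confounders=arm["correct_confounders"])
    cov = sample_covariance(res)
    pen = bool(arm.get("penalize_diagonal", False))
    if lam is None:
        lam = select_lambda_target_edges(cov, target_edges,
                                         tolerance=tolerance,
                                         penalize_diagonal=pen)
    fit = glasso_fit(cov, lam, penalize_diagonal=pen, labels=cov.labels)
    return res, fit, extract_network(fit)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full comparative study; returns (and writes) the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = _scenario_from_config(config)
    data = simulate(scenario)
    write_dataset(data, outdir / "data")
    analysis_seeds = np.random.SeedSequence(config.seed).generate_state(4)
    analysis_seeds = [int(s & 0x7FFFFFFF) for s in analysis_seeds]

    summary: dict = {
        "scenario": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in dataclasses.asdict(scenario).items()},
        "arms": [dict(a) for a in config.arms],
        "lambda_policy": config.lambda_policy,
        "networks": {},
        "comparisons": [],
        "enrichment": {},
        "errors": {},
    }

    # --- reference network fixes the common size -------------------------
    ref_arm = dict(config.arms[0])
    ref_res = residual_pipeline(
        data.counts, data.covariates, "counts",
        scale=ref_arm["scale"],
        correct_confounders=ref_arm["correct_confounders"])
    if config.lambda_policy == "ric":
        ref_lam = select_lambda_ric(ref_res, config.ric_rotations,
                                    analysis_seeds[0])
        ref_fit = glasso_fit(sample_covariance(ref_res), ref_lam,
                             penalize_diagonal=ref_arm.get(
                                 "penalize_diagonal", False),
                             labels=data.gene_ids)
        target = max(extract_network(ref_fit).number_of_edges(), 1)
    else:
        target = int(config.target_edges)
    summary["target_edges"] = target

    networks: dict[str, nx.Graph] = {}
    for arm in config.arms:
        arm = dict(arm)
        for platform in PLATFORMS:
            label = _network_label(arm["name"], platform)
            expr = data.counts if platform == "counts" else data.continuous
            try:
                res, fit, net = _fit_arm(
                    expr, data.covariates, platform, arm,
                    target_edges=target,
                    tolerance=config.edge_match_tolerance)
            except Exception as exc:  # an arm failure must not kill the run
                logger.error("arm %s failed: %s", label, exc)
                summary["errors"][label] = str(exc)
                continue
            networks[label] = net
            tag = label.replace(":", "_")
            res.values.to_csv(outdir / f"residuals_{tag}.tsv", sep="\t")
            ncio.write_precision_tsv(fit.theta, fit.labels,
                                     outdir / f"precision_{tag}.tsv")
            ncio.write_network_tsv(net, outdir / f"network_{tag}.tsv")
            # node-variance diagnostics on the unstandardised residuals
            raw = residual_pipeline(
                expr, data.covariates, platform, scale=False,
                correct_confounders=arm["correct_confounders"])
            variances = raw.values.var(axis=1, ddof=1)
            prof = degree_variance_profile(net, variances)
            prof.table.to_csv(outdir / f"degree_variance_{tag}.tsv",
                              sep="\t", index=False)
            dist = degree_distribution(net)
            summary["networks"][label] = {
                "lambda": fit.lam,
                "n_edges": net.number_of_edges(),
                "converged": fit.converged,
                "degree_variance_spearman": prof.spearman,
                "degree_gini": dist.gini,
                "max_degree": dist.max_degree,
            }

    # --- pairwise comparison table (Table-1 analogue) --------------------
    labels = sorted(networks)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            try:
                corr = graph_correlation(networks[la], networks[lb])
                p = qap_test(networks[la], networks[lb],
                             n_perm=config.qap_permutations,
                             seed=analysis_seeds[1])
            except ValueError as exc:
                summary["errors"][f"{la}|{lb}"] = str(exc)
                continue
            summary["comparisons"].append(
                {"a": la, "b": lb, "graph_correlation": corr,
                 "qap_pvalue": p})

    # --- pathway-pair enrichment -----------------------------------------
    if config.gene_sets is not None:
        collection = read_gmt(config.gene_sets)
    else:
        collection = make_random_gene_sets(
            data.gene_ids, n_sets=config.n_random_sets,
            size_range=(max(config.min_pathway_genes, 3),
                        max(6, scenario.p // 3)),
            seed=analysis_seeds[2])
        write_gmt(collection, outdir / "gene_sets.gmt")
    for label, net in networks.items():
        kept = filter_pathways(collection, net.nodes,
                               config.min_pathway_genes)
        if len(kept) < 2 or net.number_of_edges() == 0:
            continue
        results = all_pairs_enrichment(net, kept)
        tag = label.replace(":", "_")
        write_enrichment_tsv(results, outdir / f"enrichment_{tag}.tsv")
        pw_net = enrichment_network(results, alpha=config.alpha)
        ncio.write_network_tsv(pw_net, outdir / f"pathway_network_{tag}.tsv")
        qq = pvalue_qq(results)
        qq.table.to_csv(outdir / f"enrichment_qq_{tag}.tsv", sep="\t",
                        index=False)
        summary["enrichment"][label] = {
            "n_pathways": len(kept),
            "n_pairs": len(results),
            "pathway_edges": pw_net.number_of_edges(),
            "qq_ks_distance": qq.ks_distance,
        }

    if config.run_groups:
        summary["groups"] = run_group_analysis(config, data=data,
                                               outdir=outdir / "groups",
                                               target_edges=target,
                                               collection=collection)

    _write_summary(summary, outdir / "summary.json")
    return summary


def run_group_analysis(config: PipelineConfig, data=None, outdir=None,
                       target_edges: int | None = None,
                       collection=None) -> dict:
    """High- vs low-glucose networks, differential networks and their
    cross-platform intersection, with enrichment q-q diagnostics."""
    if data is None:
        data = simulate(_scenario_from_config(config))
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    cov = data.covariates
    groups = {g: cov.index[cov["group"] == g] for g in ("high", "low")}
    for g, ids in groups.items():
        if len(ids) < config.min_group_samples:
            raise ValueError(
                f"group '{g}' has {len(ids)} samples "
                f"(< {config.min_group_samples})")
    arm = dict(config.arms[0])
    seeds = np.random.SeedSequence(config.seed + 7).generate_state(2)
    seeds = [int(s & 0x7FFFFFFF) for s in seeds]

    if target_edges is None:
        if config.lambda_policy == "target":
            target_edges = int(config.target_edges)
        else:
            res = residual_pipeline(
                data.counts[groups["high"]], cov.loc[groups["high"]],
                "counts", scale=arm["scale"],
                correct_confounders=arm["correct_confounders"])
            lam = select_lambda_ric(res, config.ric_rotations, seeds[0])
            fit = glasso_fit(sample_covariance(res), lam,
                             labels=data.gene_ids)
            target_edges = max(extract_network(fit).number_of_edges(), 1)

    report: dict = {"target_edges": target_edges, "platforms": {},
                    "planted_edges": [list(e) for e in
                                      data.group_specific_edges]}
    diff_high: dict[str, nx.Graph] = {}
    diff_low: dict[str, nx.Graph] = {}
    for platform in PLATFORMS:
        expr = data.counts if platform == "counts" else data.continuous
        nets = {}
        for g, ids in groups.items():
            _, fit, net = _fit_arm(expr[ids], cov.loc[ids], platform, arm,
                                   target_edges=target_edges,
                                   tolerance=config.edge_match_tolerance)
            nets[g] = net
            if outdir is not None:
                ncio.write_network_tsv(
                    net, outdir / f"network_{platform}_{g}.tsv")
        dh = differential_network(nets["high"], nets["low"])
        dl = differential_network(nets["low"], nets["high"])
        diff_high[platform] = dh
        diff_low[platform] = dl
        if outdir is not None:
            ncio.write_network_tsv(dh, outdir / f"diff_high_{platform}.tsv")
            ncio.write_network_tsv(dl, outdir / f"diff_low_{platform}.tsv")
        entry = {
            "edges_high": nets["high"].number_of_edges(),
            "edges_low": nets["low"].number_of_edges(),
            "diff_high_edges": dh.number_of_edges(),
            "diff_low_edges": dl.number_of_edges(),
        }
        if data.group_specific_edges:
            planted = {tuple(e) for e in data.group_specific_edges}
            found = {tuple(sorted(map(str, e))) for e in dh.edges}
            entry["planted_edge_recall"] = len(planted & found) / len(planted)
        if collection is not None:
            kept = filter_pathways(collection, dh.nodes,
                                   config.min_pathway_genes)
            if len(kept) >= 2 and dh.number_of_edges() > 0:
                results = all_pairs_enrichment(dh, kept)
                qq = pvalue_qq(results)
                entry["diff_high_qq_ks"] = qq.ks_distance
                if outdir is not None:
                    qq.table.to_csv(
                        outdir / f"diff_high_qq_{platform}.tsv",
                        sep="\t", index=False)
        report["platforms"][platform] = entry

    for name, diffs in (("diff_high", diff_high), ("diff_low", diff_low)):
        inter = multi_network_intersection(*diffs.values())
        report[f"{name}_intersection_edges"] = inter.number_of_edges()
        if outdir is not None:
            ncio.write_network_tsv(inter,
                                   outdir / f"{name}_intersection.tsv")
    if outdir is not None:
        _write_summary(report, outdir / "group_summary.json")
    return report


def _write_summary(summary: dict, path) -> None:
    Path(path).write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
        + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
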