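"""Pathway-pair network enrichment (NEAT-style hypergeometric test).

Networks of thousands of genes replicate poorly edge-by-edge across
platforms; summarising them at the level of gene-set (pathway) pairs is far
more robust.  For two gene sets A and B on a network with m edges, the test
asks whether the number of edges connecting A and B exceeds what a
degree-aware random graph would produce.

Null model: o_AB half-edges leaving A are thought of as d_A draws without
replacement from the 2m half-edge stubs, d_B of which belong to B (d_A, d_B
are the summed node degrees on the full network).  Then

    O ~ Hypergeom(N = 2m, K = d_B, n = d_A),
    E[O] = d_A * d_B / (2m),
    p = P(O >= o_AB)   (over-enrichment, upper tail).

This is the configuration-model expectation; its adequacy is validated
against a degree-preserving rewiring oracle in the test suite rather than
asserted.  Overlapping sets: an edge counts toward o_AB once if it joins a
node of A to a node of B, except edges lying entirely inside the overlap,
which are excluded to avoid double counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets, order-preserving, with a provenance note."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class EnrichmentResult:
    set_a: str
    set_b: str
    observed: int  # o_AB
    expected: float  # mu_AB
    pvalue: float
    degree_a: int
    degree_b: int
    n_edges: int  # m
    degenerate: bool = False


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> member genes."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}: malformed GMT line {ln} (need name, description "
                f"and at least one gene)"
            )
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r} "
                             f"at line {ln}")
        seen: list[str] = []
        for g in parts[2:]:
            if g and g not in seen:
                seen.append(g)
        sets[name] = seen
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def filter_pathways(collection: GeneSetCollection, network_nodes,
                    min_genes: int = 20) -> GeneSetCollection:
    """Keep sets with >= min_genes members among the network nodes;
    members are restricted to the node set."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    nodes = {str(n) for n in network_nodes}
    kept: dict[str, list[str]] = {}
    for name, genes in collection.sets.items():
        members = [g for g in genes if g in nodes]
        if len(members) >= min_genes:
            kept[name] = members
    if not kept:
        logger.warning("no gene sets survive the >= %d gene filter", min_genes)
    return GeneSetCollection(sets=kept,
                             provenance=collection.provenance
                             + f" | filtered min_genes={min_genes}")


# ---------------------------------------------------------------------------
# the enrichment test
# ---------------------------------------------------------------------------

def connecting_edges(network: nx.Graph, genes_a, genes_b) -> int:
    """Edges joining A to B, counting each edge once and excluding edges
    that lie entirely within the overlap A∩B."""
    sa, sb = set(genes_a), set(genes_b)
    both = sa & sb
    o = 0
    for u, v in network.edges:
        if u == v:
            continue
        if u in both and v in both:
            continue
        if (u in sa and v in sb) or (u in sb and v in sa):
            o += 1
    return o


def neat_overenrichment(network: nx.Graph, genes_a, genes_b,
                        name_a: str = "A", name_b: str = "B"
                        ) -> EnrichmentResult:
    """Hypergeometric over-enrichment test for edges between two gene sets."""
    if name_a == name_b:
        raise ValueError("the two sets must have distinct names")
    nodes = set(network.nodes)
    sa = [g for g in genes_a if g in nodes]
    sb = [g for g in genes_b if g in nodes]
    m = network.number_of_edges()
    if m == 0:
        raise ValueError("enrichment undefined on an edgeless network")
    deg = dict(network.degree)
    d_a = int(sum(deg[g] for g in sa))
    d_b = int(sum(deg[g] for g in sb))
    o = connecting_edges(network, sa, sb)
    mu = d_a * d_b / (2.0 * m)
    if d_a == 0 or d_b == 0:
        return EnrichmentResult(name_a, name_b, o, mu, 1.0, d_a, d_b, m,
                                degenerate=True)
    # P(O >= o) under O ~ Hypergeom(N=2m, K=d_b, n=d_a)
    p = float(stats.hypergeom.sf(o - 1, 2 * m, d_b, d_a))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(name_a, name_b, o, mu, p, d_a, d_b, m)


def all_pairs_enrichment(network: nx.Graph,
                         collection: GeneSetCollection
                         ) -> list[EnrichmentResult]:
    """Over-enrichment test for every unordered pair of sets, ranked by p."""
    names = collection.names()
    if len(names) < 2:
        raise ValueError("need at least two gene sets")
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            results.append(
                neat_overenrichment(network,
                                    collection.sets[names[i]],
                                    collection.sets[names[j]],
                                    names[i], names[j]))
    results.sort(key=lambda r: (r.pvalue, r.set_a, r.set_b))
    return results


def enrichment_network(results: list[EnrichmentResult],
                       alpha: float = 0.10,
                       bh_adjust: bool = False) -> nx.Graph:
    """Pathway-level network: edge (A, B) iff the pair is over-enriched.

    By default raw p-values are thresholded at ``alpha`` (no multiplicity
    correction); ``bh_adjust=True`` applies Benjamini-Hochberg first.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    names = sorted({r.set_a for r in results} | {r.set_b for r in results})
    G = nx.Graph()
    G.add_nodes_from(names)
    pvals = np.array([r.pvalue for r in results])
    if bh_adjust:
        pvals = _bh(pvals)
    for r, p in zip(results, pvals):
        if p < alpha:
            G.add_edge(r.set_a, r.set_b, pvalue=float(r.pvalue),
                       observed=r.observed, expected=r.expected)
    return G


def _bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# q-q diagnostics
# ---------------------------------------------------------------------------

@dataclass
class QQTable:
    table: pd.DataFrame  # columns: expected, observed
    ks_distance: float


def pvalue_qq(results) -> QQTable:
    """Sorted p-values against uniform quantiles (i - 0.5)/m.

    Under no enrichment p-values are uniform and the q-q curve follows the
    diagonal; a right-skewed (below-diagonal) curve indicates enrichment
    signal.  The Kolmogorov-Smirnov distance to the uniform is reported.
    """
    if results and isinstance(results[0], EnrichmentResult):
        p = np.array([r.pvalue for r in results], dtype=float)
    else:
        p = np.asarray(results, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    p = np.sort(p)
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    ks = float(stats.kstest(p, "uniform").statistic)
    return QQTable(
        table=pd.DataFrame({"expected": expected, "observed": p}),
        ks_distance=ks,
    )


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame(
        [
            {
                "set_a": r.set_a, "set_b": r.set_b, "observed": r.observed,
                "expected": r.expected, "pvalue": r.pvalue,
                "degree_a": r.degree_a, "degree_b": r.degree_b,
                "n_edges": r.n_edges,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def make_random_gene_sets(genes, n_sets: int = 12,
                          size_range: tuple[int, int] = (10, 25),
                          seed: int = 0,
                          prefix: str = "SET") -> GeneSetCollection:
    """Random gene sets (drawn independently of any network) — a null
    collection for calibration studies and demonstrations."""
    genes = [str(g) for g in genes]
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 1 or hi < lo or lo > len(genes):
        raise ValueError("invalid size range for the available genes")
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"{prefix}{k + 1:03d}"] = [genes[i] for i in sorted(members)]
    return GeneSetCollection(sets=sets, provenance="synthetic random sets")
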