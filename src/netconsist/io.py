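"""Plain-text readers and writers for expression, covariate and network tables.

Expression TSV: first column ``gene_id``, remaining columns sample ids;
counts are written as integers.  Covariates TSV: first column ``sample_id``.
Networks are stored as tab-separated edge lists
``gene_a<TAB>gene_b<TAB>partial_correlation``; since an edge list cannot
carry isolated nodes, readers accept an optional node list to restore the
full node set (network comparisons require identical node sets).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_expression_tsv(df: pd.DataFrame, path, integer: bool = False) -> None:
    out = df.round(0).astype(np.int64) if integer else df
    out = out.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    if df.isna().any().any():
        raise ValueError(f"covariate table {path} contains missing values")
    return df


def write_covariates_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_network_tsv(G: nx.Graph, path) -> None:
    rows = []
    for a, b, data in sorted(G.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        a, b = sorted((str(a), str(b)))
        rows.append((a, b, data.get("weight", np.nan)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "partial_correlation"])
    df.to_csv(path, sep="\t", index=False)


def read_network_tsv(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    G = nx.Graph()
    if nodes is not None:
        G.add_nodes_from(str(n) for n in nodes)
    for _, row in df.iterrows():
        G.add_edge(row["gene_a"], row["gene_b"],
                   weight=float(row.get("partial_correlation", np.nan)))
    return G


def write_precision_tsv(theta: np.ndarray, labels, path) -> None:
    pd.DataFrame(theta, index=labels, columns=labels).to_csv(path, sep="\t")


def read_node_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]
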