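"""Confidence-filtered protein-protein interaction network and hub genes.

Edges are kept when both endpoints belong to the gene list and the combined
confidence score is strictly greater than the cutoff (0.9 by default,
STRING's "highest confidence" band). Degree is computed on this induced
subgraph; hub genes are the top 15% of degree values, ties at the boundary
included.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


def read_edges(path: str | Path, string_scale: bool = False) -> pd.DataFrame:
    """TSV with columns gene_a, gene_b, confidence. With string_scale=True
    the third column is a STRING combined score in [0, 1000] and is divided
    by 1000."""
    table = pd.read_csv(path, sep="\t")
    table.columns = ["gene_a", "gene_b", "confidence", *table.columns[3:]]
    if string_scale:
        table["confidence"] = table["confidence"] / 1000.0
    return table


def build_network(edges: pd.DataFrame, gene_list: list[str],
                  min_confidence: float = 0.9) -> nx.Graph:
    """Induced undirected network over gene_list at confidence > cutoff.

    Self-loops are dropped; duplicate edges keep the maximum confidence.
    Listed genes with no surviving edge stay in the graph with degree 0.
    Malformed confidence values reject the row with a log line.
    """
    listed = {str(g).upper() for g in gene_list}
    net = nx.Graph()
    net.add_nodes_from(sorted(listed))
    for row in edges.itertuples(index=False):
        a, b = str(row.gene_a).upper(), str(row.gene_b).upper()
        try:
            conf = float(row.confidence)
        except (TypeError, ValueError):
            log.info("rejecting edge %s-%s: malformed score %r",
                     a, b, row.confidence)
            continue
        if not (0.0 <= conf <= 1.0):
            log.info("rejecting edge %s-%s: score %g outside [0, 1]",
                     a, b, conf)
            continue
        if a == b or a not in listed or b not in listed:
            continue
        if conf > min_confidence:   # strictly greater
            if net.has_edge(a, b):
                conf = max(conf, net[a][b]["confidence"])
            net.add_edge(a, b, confidence=conf)
    return net


def hub_genes(net: nx.Graph, top_fraction: float = 0.15) -> list[str]:
    """Nodes in the top fraction of degree values.

    k = ceil(top_fraction * n_nodes); nodes tied with the k-th degree are
    all included. Ordered by descending degree, then symbol.
    """
    if net.number_of_nodes() == 0:
        return []
    ordered = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(top_fraction * len(ordered))
    cutoff = ordered[k - 1][1]
    return [g for g, d in ordered if d >= cutoff]


def degree_table(net: nx.Graph) -> pd.DataFrame:
    rows = sorted(net.degree(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"])


def write_network(net: nx.Graph, path: str | Path) -> None:
    rows = [(a, b, net[a][b]["confidence"])
            for a, b in sorted(net.edges())]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]) \
        .to_csv(path, sep="\t", index=False)
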