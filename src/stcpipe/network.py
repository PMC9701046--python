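"""Gene co-expression network over a selected gene list.

Edges connect gene pairs whose Pearson correlation of log2 signals across
all samples (all groups jointly — the trajectory is the signal) reaches a
threshold in absolute value; the edge keeps the signed correlation as its
weight.  Per-node summaries follow the usual graph vocabulary:

* degree — number of neighbors, the hub criterion;
* clustering coefficient — 2*e_i / (k_i*(k_i - 1)), the edge density among
  a node's neighbors (0 by convention for degree < 2);
* k-core — the largest k such that the node survives iterative removal of
  all nodes of degree < k.

Hubs are ranked by degree (descending), ties by clustering coefficient
then gene id.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("stcpipe")


def build_network(matrix: ExpressionMatrix, genes: Sequence[str] | None = None,
                  threshold: float = 0.8,
                  profile_labels: Mapping[str, int] | None = None) -> nx.Graph:
    """Threshold the gene-gene correlation matrix into a simple graph.

    Pearson correlations are computed on log2 signals across all samples;
    an edge is drawn when ``|r| >= threshold``.  Constant genes (undefined
    correlation) are dropped with a warning.  Node attribute ``profile``
    is attached when ``profile_labels`` is given.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    sub = matrix if genes is None else matrix.subset(genes)
    if sub.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate")
    if sub.n_genes < 2:
        raise ValueError("need at least 2 genes to build a network")

    log2 = sub.log2_values().to_numpy(dtype=float)
    ids = list(sub.values.index)
    constant = log2.std(axis=1) == 0
    if constant.any():
        dropped = [g for g, c in zip(ids, constant) if c]
        logger.warning("dropping %d constant gene(s) from the network: %s",
                       len(dropped), dropped[:10])
        log2 = log2[~constant]
        ids = [g for g, c in zip(ids, constant) if not c]

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    if len(ids) >= 2:
        corr = np.corrcoef(log2)
        iu, ju = np.triu_indices(len(ids), k=1)
        keep = np.abs(corr[iu, ju]) >= threshold
        graph.add_weighted_edges_from(
            (ids[i], ids[j], float(corr[i, j]))
            for i, j in zip(iu[keep], ju[keep])
        )
    if profile_labels is not None:
        nx.set_node_attributes(
            graph,
            {g: int(profile_labels[g]) for g in graph.nodes
             if g in profile_labels},
            "profile",
        )
    return graph


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Degree, clustering coefficient and k-core for every node.

    Empty graph gives an empty table.  Self-loops are not expected (the
    builder never makes them) but are removed defensively since core
    numbers are undefined with them.
    """
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene", "degree", "clustering", "k_core"])
    g = graph
    if nx.number_of_selfloops(g):
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    clustering = nx.clustering(g)
    core = nx.core_number(g)
    return pd.DataFrame(
        {
            "gene": list(g.nodes),
            "degree": [g.degree(v) for v in g.nodes],
            "clustering": [clustering[v] for v in g.nodes],
            "k_core": [core[v] for v in g.nodes],
        }
    )


def rank_hubs(metrics: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Top-``top_k`` nodes by degree, ties by clustering then gene id."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ranked = metrics.sort_values(
        ["degree", "clustering", "gene"], ascending=[False, False, True],
        kind="mergesort", ignore_index=True,
    )
    return ranked.head(top_k)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edges as TSV (gene_i, gene_j, r), deterministic order."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tr\n")
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
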