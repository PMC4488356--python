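"""Degree-based hub biomarker selection on a restricted interaction network.

The network is the induced subgraph of the integrated protein-interaction
edge list on the resistance-related node set (candidate genes from the
significant pathways plus the common resistance genes).  Node degrees are
converted with the base-2 logarithm and genes with log2(degree) strictly
greater than the threshold (default 4.7, i.e. at least ~26 neighbors) are
selected as hub biomarkers.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .errors import InputError

__all__ = ["build_network", "node_degrees", "select_biomarkers", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 4.7


def build_network(interactions: set[tuple[str, str]], node_set) -> nx.Graph:
    """Induced simple undirected subgraph on ``node_set``."""
    nodes = set(node_set)
    if not nodes:
        raise InputError("node_set must be nonempty")
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    g.add_edges_from(
        (a, b) for a, b in interactions if a != b and a in nodes and b in nodes
    )
    return g


def node_degrees(network: nx.Graph) -> pd.DataFrame:
    """Per-node degree and log2(degree); isolated nodes carry NaN log-degree."""
    genes = sorted(network.nodes)
    deg = np.array([network.degree[g] for g in genes], dtype=float)
    with np.errstate(divide="ignore"):
        log2d = np.where(deg >= 1, np.log2(np.maximum(deg, 1)), np.nan)
    return pd.DataFrame(
        {"degree": deg.astype(int), "log2_degree": log2d},
        index=pd.Index(genes, name="gene_id"),
    )


def select_biomarkers(degrees: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> list[str]:
    """Genes with log2(degree) strictly above the threshold.

    Sorted by descending degree, then lexicographic gene id.  Isolated
    nodes (NaN log-degree) are never selected.
    """
    mask = (degrees["log2_degree"] > threshold).fillna(False)
    selected = degrees.loc[mask]
    # stable sort: lexicographic first, then by descending degree
    order = selected.sort_index().sort_values("degree", ascending=False, kind="mergesort")
    return order.index.tolist()
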