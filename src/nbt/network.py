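"""PPI graph construction and the virtual phenotype node.

The interaction graph is an undirected, unweighted networkx graph over gene
symbols, built from STRING-style scored edges at a confidence cutoff
(default combined_score >= 700, STRING's high-confidence convention). The
augmented graph used by the embedding strategy carries one extra *virtual
phenotype node* wired to every anchor gene present in the graph; heat
diffusion runs on the plain graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: node label reserved for the virtual phenotype node
VIRTUAL_NODE = "__PHENOTYPE__"

__all__ = ["VIRTUAL_NODE", "AugmentedGraph", "build_ppi_graph",
           "add_virtual_node", "laplacian"]


@dataclass
class AugmentedGraph:
    """A PPI graph plus the virtual phenotype node.

    ``graph`` contains the gene-gene edges of the base graph and the extra
    star from ``virtual_node`` to every anchor found in the base graph;
    ``missing_anchors`` counts requested anchors absent from the graph.
    """

    graph: nx.Graph
    virtual_node: str
    anchors_in_graph: list[str]
    missing_anchors: int


def build_ppi_graph(edges: Iterable[tuple[str, str, int]],
                    score_min: int = 700) -> nx.Graph:
    """Build the undirected PPI graph from scored edges.

    Keeps edges with combined_score >= ``score_min``, drops self-loops, and
    restricts the graph to nodes with degree >= 1 (isolated nodes cannot
    arise from an edge list). Edge scores are stored as the ``score``
    attribute; the graph itself is treated as unweighted downstream.
    """
    edges = list(edges)
    if not edges:
        raise ValidationError("empty edge list")
    g = nx.Graph()
    for a, b, s in edges:
        if a == b:
            continue
        if s >= score_min:
            # parallel edges collapse; keep the larger score
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=int(s))
    if g.number_of_edges() == 0:
        raise ValidationError(
            f"no edge reaches combined_score >= {score_min}; lower the threshold"
        )
    n_comp = nx.number_connected_components(g)
    logger.info("PPI graph: %d nodes, %d edges, %d connected component(s)",
                g.number_of_nodes(), g.number_of_edges(), n_comp)
    return g


def add_virtual_node(graph: nx.Graph, anchors: Sequence[str],
                     virtual_node: str = VIRTUAL_NODE) -> AugmentedGraph:
    """Attach the virtual phenotype node to every anchor present in the graph."""
    if virtual_node in graph:
        raise ValidationError(f"virtual node label {virtual_node!r} collides with a gene")
    present = [a for a in anchors if a in graph]
    missing = len(list(anchors)) - len(present)
    if not present:
        raise ValidationError("no anchor gene maps to a node of the PPI graph")
    if missing:
        logger.warning("%d anchor(s) not found in the PPI graph", missing)
    aug = graph.copy()
    aug.add_node(virtual_node)
    aug.add_edges_from((virtual_node, a) for a in present)
    return AugmentedGraph(aug, virtual_node, present, missing)


def laplacian(graph: nx.Graph, nodelist: Sequence[str] | None = None) -> sp.csr_array:
    """Unnormalised graph Laplacian L = D - A over binarised adjacency.

    Node order follows ``nodelist`` (default: sorted node labels) so results
    are deterministic regardless of insertion order.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph has no Laplacian")
    if nodelist is None:
        nodelist = sorted(graph.nodes)
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodelist, weight=None,
                                   format="csr").astype(float)
    deg = sp.diags_array(np.asarray(adj.sum(axis=1)).ravel(), format="csr")
    return deg - adj
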