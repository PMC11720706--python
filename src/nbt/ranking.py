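"""Phenotype-relevance gene ranking: node embedding and heat diffusion.

Two alternative strategies turn an anchored PPI graph into a ranked gene
list:

* **Node embedding** — uniform random walks over the augmented graph (the
  virtual phenotype node wired to all anchors) feed a skip-gram
  negative-sampling trainer; genes are ranked by cosine similarity of their
  vector to the virtual node's vector.
* **Heat diffusion** — the anchor indicator vector h is diffused on the
  plain PPI graph as d = exp(-Lt) h with L = D - A; genes are ranked by
  their heat value. t (default 0.1, the common network-propagation default)
  controls how far the signal spreads.

Both produce a deterministic ranked list (descending score, ties broken by
gene symbol, ranks starting at 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.linalg import expm_multiply

from ._sgns import train_sgns
from .exceptions import ValidationError
from .network import VIRTUAL_NODE, AugmentedGraph, laplacian

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingConfig", "HeatVector", "make_ranked_list", "generate_walks",
           "train_embeddings", "rank_by_embedding", "diffuse", "rank_by_heat"]


@dataclass
class EmbeddingConfig:
    """DeepWalk/word2vec hyperparameters for the embedding strategy.

    Defaults follow the usual DeepWalk-on-PPI settings: 100 walks per node of
    6 nodes each, 256-dimensional skip-gram vectors, window 4, 10 negative
    samples, learning rate decaying linearly 0.03 -> 0.0007 over 50 epochs.
    """

    walks_per_node: int = 100
    walk_length: int = 6  # nodes per walk, start node included
    vector_size: int = 256
    window: int = 4
    skipgram: bool = True
    negative: int = 10
    lr_initial: float = 0.03
    lr_final: float = 0.0007
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("walks_per_node", "walk_length", "vector_size", "window",
                     "negative", "epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.lr_final >= self.lr_initial:
            raise ValidationError("lr_final must be below lr_initial")
        if not self.skipgram:
            raise ValidationError("only the skip-gram objective is implemented")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HeatVector:
    """Per-node heat after diffusion for time t; total heat equals the query total."""

    nodes: list[str]
    heat: np.ndarray
    t: float
    query_total: float = field(default=0.0)

    def as_series(self) -> pd.Series:
        return pd.Series(self.heat, index=self.nodes, name="heat")


def make_ranked_list(scores: Mapping[str, float]) -> pd.DataFrame:
    """Deterministic ranked list: descending score, ties by gene symbol, rank from 1."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({
        "gene": [g for g, _ in items],
        "score": [s for _, s in items],
        "rank": np.arange(1, len(items) + 1),
    })


def generate_walks(graph: nx.Graph | AugmentedGraph,
                   cfg: EmbeddingConfig) -> list[list[str]]:
    """Uniform random walks: ``walks_per_node`` walks of ``walk_length`` nodes per start.

    Degree-0 nodes are skipped with a warning. Corpus order is deterministic
    given the seed (start nodes in sorted order).
    """
    g = graph.graph if isinstance(graph, AugmentedGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    rng = np.random.default_rng(cfg.seed)
    neighbors = {node: sorted(g.neighbors(node)) for node in g.nodes}
    walks: list[list[str]] = []
    for start in sorted(g.nodes):
        nbrs = neighbors[start]
        if not nbrs:
            logger.warning("skipping isolated node %r", start)
            continue
        for _ in range(cfg.walks_per_node):
            walk = [start]
            cur = start
            for _ in range(cfg.walk_length - 1):
                opts = neighbors[cur]
                cur = opts[rng.integers(len(opts))]
                walk.append(cur)
            walks.append(walk)
    return walks


def train_embeddings(corpus: list[list[str]],
                     cfg: EmbeddingConfig) -> dict[str, np.ndarray]:
    """Skip-gram negative-sampling embeddings for every node in the corpus."""
    return train_sgns(
        corpus,
        vector_size=cfg.vector_size,
        window=cfg.window,
        negative=cfg.negative,
        epochs=cfg.epochs,
        lr_initial=cfg.lr_initial,
        lr_final=cfg.lr_final,
        seed=cfg.seed,
    )


def rank_by_embedding(vectors: Mapping[str, np.ndarray],
                      virtual_node: str = VIRTUAL_NODE) -> pd.DataFrame:
    """Rank genes by cosine similarity of their vector to the virtual node's."""
    if virtual_node not in vectors:
        raise ValidationError(f"virtual node {virtual_node!r} has no embedding vector")
    ref = np.asarray(vectors[virtual_node], dtype=float)
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValidationError("virtual node embedding has zero norm")
    scores: dict[str, float] = {}
    for gene, vec in vectors.items():
        if gene == virtual_node:
            continue
        v = np.asarray(vec, dtype=float)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            logger.warning("zero-norm vector for %r; scored -1", gene)
            scores[gene] = -1.0
        else:
            scores[gene] = float(ref @ v / (ref_norm * nrm))
    return make_ranked_list(scores)


def diffuse(graph: nx.Graph, anchors: Sequence[str], t: float = 0.1,
            query_mode: str = "unit") -> HeatVector:
    """Heat diffusion d = exp(-Lt) h from the anchor set.

    h is the anchor indicator vector (``query_mode="unit"``) or the
    indicator divided by the number of anchors (``"normalized"``; rankings
    are identical since exp(-Lt) is linear). The matrix exponential is
    applied as an action on h, never materialised.
    """
    if t < 0:
        raise ValidationError(f"diffusion time must be non-negative, got {t}")
    if query_mode not in ("unit", "normalized"):
        raise ValidationError(f"unknown query_mode {query_mode!r}")
    nodes = sorted(graph.nodes)
    present = [a for a in anchors if a in graph]
    if not present:
        raise ValidationError("no anchor gene maps to a node of the PPI graph")
    h = np.zeros(len(nodes))
    pos = {n: i for i, n in enumerate(nodes)}
    for a in present:
        h[pos[a]] = 1.0
    if query_mode == "normalized":
        h /= len(present)
    if t == 0:
        d = h.copy()
    else:
        lap = laplacian(graph, nodelist=nodes)
        d = expm_multiply(lap * (-t), h)
    return HeatVector(nodes, d, t, query_total=float(h.sum()))


def rank_by_heat(heat: HeatVector) -> pd.DataFrame:
    """Rank genes by descending heat value (deterministic tie-break)."""
    if not np.all(np.isfinite(heat.heat)):
        raise ValidationError("heat vector contains non-finite values")
    return make_ranked_list(dict(zip(heat.nodes, heat.heat)))
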