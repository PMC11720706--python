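"""Functional co-occurrence of gene signatures.

Each signature is scored per sample with single-sample gene-set enrichment
(ssGSEA): genes are ranked by descending expression within the sample and
the score is the integrated difference between the weighted in-set ECDF
(weight = rank statistic ** alpha, alpha = 0.25) and the uniform out-of-set
ECDF. Pearson correlation of the score profiles quantifies co-occurrence
between signatures, and average-linkage hierarchical clustering on the
distance 1 - r groups them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import ValidationError
from .io import ExpressionMatrix

__all__ = ["SsgseaScoreTable", "ssgsea_scores", "cooccurrence_matrix",
           "cluster_signatures"]


@dataclass
class SsgseaScoreTable:
    """Signature x sample enrichment scores."""

    scores: pd.DataFrame
    alpha: float = 0.25


def _sample_es(order_desc: np.ndarray, rank_value: np.ndarray,
               in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment score for one sample.

    ``order_desc`` indexes genes by descending expression, ``rank_value`` is
    the per-gene rank statistic (G for the top gene down to 1), ``in_set``
    flags set membership per gene.
    """
    members = in_set[order_desc]
    weights = np.where(members, rank_value[order_desc] ** alpha, 0.0)
    denom_in = weights.sum()
    n_out = len(order_desc) - members.sum()
    p_in = np.cumsum(weights) / denom_in
    p_out = np.cumsum(~members) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(expr: ExpressionMatrix, gene_sets: Mapping[str, Sequence[str]],
                  alpha: float = 0.25) -> SsgseaScoreTable:
    """Per-sample ssGSEA enrichment score of every gene set.

    Each set must overlap the matrix in at least 2 genes and leave a
    non-empty complement.
    """
    genes = np.asarray(expr.genes)
    n_genes = len(genes)
    memberships: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        mask = np.isin(genes, list(members))
        if mask.sum() < 2:
            raise ValidationError(
                f"gene set {name!r} overlaps the matrix in {int(mask.sum())} "
                "gene(s); need at least 2")
        if mask.all():
            raise ValidationError(f"gene set {name!r} covers every gene (empty complement)")
        memberships[name] = mask

    out = np.empty((len(memberships), len(expr.samples)))
    for j in range(len(expr.samples)):
        col = expr.values[:, j]
        order = np.argsort(-col, kind="stable")
        rank_value = np.empty(n_genes)
        rank_value[order] = np.arange(n_genes, 0, -1)
        for i, mask in enumerate(memberships.values()):
            out[i, j] = _sample_es(order, rank_value, mask, alpha)
    return SsgseaScoreTable(
        pd.DataFrame(out, index=list(memberships), columns=expr.samples), alpha)


def cooccurrence_matrix(scores: SsgseaScoreTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of signature score profiles across samples."""
    df = scores.scores if isinstance(scores, SsgseaScoreTable) else scores
    if df.shape[1] < 3:
        raise ValidationError("need at least 3 samples for correlation")
    variances = df.var(axis=1)
    flat = variances[variances == 0].index.tolist()
    if flat:
        raise ValidationError(f"zero-variance score rows: {flat}")
    corr = np.corrcoef(df.to_numpy())
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=df.index, columns=df.index)


def cluster_signatures(corr: pd.DataFrame, k: int = 3) -> pd.Series:
    """Average-linkage hierarchical clustering on distance 1 - r, cut at k clusters."""
    n = corr.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip((dist + dist.T) / 2, 0, None), checks=False)
    labels = fcluster(linkage(condensed, method="average"), t=k, criterion="maxclust")
    return pd.Series(labels, index=corr.index, name="cluster")
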