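"""Greedy hindering/helpful signature selection from a ranked gene list.

Starting from the top-k candidates of a network ranking (default k = 150),
the selection sweeps the pool in rank order, growing a working set: a gene
whose addition raises the cross-validated C-index of the working set is
labelled *helpful* and kept, otherwise it is labelled *hindering*. At the
end of a sweep the pool is replaced by the helpful genes and the sweep
repeats, until the pool size no longer changes; the fixed-point set is the
signature. The CV folds are drawn once per run and reused for every
evaluation, so the procedure is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coxph import cox_newton
from .exceptions import ConvergenceError, EmptySignatureError, ValidationError
from .io import ClinicalTable, ExpressionMatrix
from .survival import _align, _cv_cindex, _stratified_folds

logger = logging.getLogger(__name__)

__all__ = ["CandidatePool", "GeneSignature", "truncate_candidates", "greedy_select"]


@dataclass
class CandidatePool:
    """Rank-ordered candidate genes restricted to the training matrix."""

    genes: list[str]
    k_requested: int
    n_absent: int

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSignature:
    """A selected gene set plus provenance of the selection run."""

    name: str
    genes: list[str]
    method: str = "netHD"
    k: int = 150
    seed: int = 0
    n_iterations: int = 0
    cv_cindex: float | None = None
    trace: list[dict] = field(default_factory=list, repr=False)

    def to_gmt_entry(self) -> dict[str, list[str]]:
        return {self.name: list(self.genes)}


def truncate_candidates(ranked: pd.DataFrame, expr: ExpressionMatrix,
                        k: int = 150) -> CandidatePool:
    """Top-k of the ranked list intersected with the expression genes, order kept."""
    if k < 1:
        raise ValidationError("k must be at least 1")
    genes = ranked["gene"].tolist()
    if k > len(genes):
        logger.warning("k=%d exceeds ranked list length %d; using whole list",
                       k, len(genes))
    top = genes[:k]
    have = set(expr.genes)
    pool = [g for g in top if g in have]
    n_absent = len(top) - len(pool)
    if n_absent:
        logger.info("%d of the top %d candidates absent from expression matrix",
                    n_absent, len(top))
    if not pool:
        raise ValidationError("no candidate gene present in the expression matrix")
    return CandidatePool(pool, k, n_absent)


def greedy_select(pool: CandidatePool, expr: ExpressionMatrix,
                  clinical: ClinicalTable, folds: int = 10, seed: int = 0,
                  name: str = "signature", method: str = "netHD") -> GeneSignature:
    """Run the hindering/helpful iteration to a fixed point.

    Raises :class:`EmptySignatureError` if no gene survives; a Cox failure
    while evaluating a candidate marks that candidate hindering.
    """
    if len(pool) == 0:
        raise ValidationError("empty candidate pool")
    X_all, time, event, _ = _align(expr, pool.genes, clinical)
    n, n_events = len(time), int(event.sum())
    if n < 20 or n_events < 5:
        raise ValidationError(
            f"need >= 20 samples with >= 5 events for stable selection "
            f"(got n={n}, events={n_events})")
    col_of = {g: i for i, g in enumerate(pool.genes)}

    current = list(pool.genes)
    trace: list[dict] = []
    iteration = 0
    for iteration in range(1, len(pool) + 1):
        # Fresh (deterministically seeded) folds each iteration: re-evaluating
        # the survivors under new folds is what prunes genes that only helped
        # by chance; with folds frozen across iterations the second sweep
        # would replay the first one's decisions verbatim and never reduce.
        iter_seed = int(np.random.SeedSequence([seed, iteration]).generate_state(1)[0]
                        % 2**31)
        fold_tests = _stratified_folds(event, folds, iter_seed)

        def cv_of(genes: list[str]) -> float:
            cols = [col_of[g] for g in genes]
            return _cv_cindex(X_all[:, cols], time, event, fold_tests)[0]

        working: list[str] = []
        current_c = 0.5  # empty working set baseline
        labels: dict[str, str] = {}
        for gene in current:
            try:
                c_with = cv_of(working + [gene])
            except (ConvergenceError, np.linalg.LinAlgError):
                logger.warning("Cox failure evaluating %r; labelled hindering", gene)
                labels[gene] = "hindering"
                continue
            if c_with > current_c:
                working.append(gene)
                current_c = c_with
                labels[gene] = "helpful"
            else:
                labels[gene] = "hindering"
        trace.append({"iteration": iteration, "pool_size": len(current),
                      "kept": len(working), "cv_cindex": current_c,
                      "labels": labels})
        if len(working) == len(current):
            current = working
            break
        current = working
        if not current:
            break
    if not current:
        raise EmptySignatureError(
            "greedy selection reached an empty fixed point; consider a larger "
            "candidate pool or a lower anchor threshold")
    return GeneSignature(name=name, genes=current, method=method, k=pool.k_requested,
                         seed=seed, n_iterations=iteration,
                         cv_cindex=trace[-1]["cv_cindex"], trace=trace)
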