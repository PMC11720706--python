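"""Anchor-gene identification from ordinal immunotherapy response.

A gene is an *anchor* when its expression varies monotonically with the
mRECIST response grade across patients. The consistency index of gene g is

    C_g = #{ pairs (i, j) : (g_i - g_j)(r_i - r_j) > 0 } / C(N, 2)

i.e. the fraction of unordered patient pairs whose expression difference has
the same sign as their response-grade difference. Pairs tied in either
quantity count in the denominator only, so C_g is a rank statistic over
untied pairs and penalises ties. Genes with C_g strictly above the threshold
(default 0.6) are selected as anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: mRECIST label -> ordinal grade (best response = highest grade).
GRADE_MAP = {"PD": 1, "SD": 2, "PR": 3, "CR": 4}

__all__ = ["GRADE_MAP", "ResponseGrades", "AnchorResult", "encode_response",
           "consistency_index", "select_anchors"]


@dataclass
class ResponseGrades:
    """Per-sample ordinal response grade (PD=1, SD=2, PR=3, CR=4)."""

    samples: list[str]
    grades: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.grades = np.asarray(self.grades, dtype=int)
        if len(self.samples) != len(self.grades):
            raise ValidationError("samples and grades length mismatch")
        if not np.isin(self.grades, [1, 2, 3, 4]).all():
            raise ValidationError("grades must lie in {1, 2, 3, 4}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class AnchorResult:
    """Per-gene consistency values and the selected anchor set."""

    consistency: pd.Series  # indexed by gene, descending C_g then gene symbol
    threshold: float
    anchors: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.consistency.index,
            "consistency": self.consistency.to_numpy(),
            "is_anchor": [g in set(self.anchors) for g in self.consistency.index],
        })


def encode_response(labels: Sequence[str], samples: Sequence[str] | None = None
                    ) -> ResponseGrades:
    """Map mRECIST labels to the fixed digital scale CR=4, PR=3, SD=2, PD=1."""
    grades = []
    for lab in labels:
        if lab not in GRADE_MAP:
            raise ValidationError(f"unknown mRECIST label {lab!r}")
        grades.append(GRADE_MAP[lab])
    if samples is None:
        samples = [f"S{i}" for i in range(len(grades))]
    return ResponseGrades(list(samples), np.array(grades))


def consistency_index(expr_row: np.ndarray, grades: ResponseGrades | np.ndarray) -> float:
    """Consistency C_g of one gene's expression with the response grades.

    Counts unordered pairs with a strictly positive product of differences;
    ties in expression or grade stay in the C(N,2) denominator.
    """
    g = np.asarray(expr_row, dtype=float)
    r = grades.grades if isinstance(grades, ResponseGrades) else np.asarray(grades)
    if g.shape != r.shape:
        raise ValidationError(f"expression ({g.shape}) and grades ({r.shape}) mismatch")
    n = len(g)
    if n < 2:
        raise ValidationError("need at least 2 samples to form a pair")
    iu, ju = np.triu_indices(n, k=1)
    concordant = ((g[iu] - g[ju]) * (r[iu] - r[ju]) > 0).sum()
    return float(concordant) / (n * (n - 1) // 2)


def _consistency_matrix(values: np.ndarray, grades: np.ndarray) -> np.ndarray:
    """Vectorised C_g for every row of a genes x samples matrix."""
    n = values.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    grade_diff = (grades[iu] - grades[ju]).astype(float)
    n_pairs = n * (n - 1) // 2
    out = np.empty(values.shape[0])
    # chunked to bound the G x C(N,2) intermediate
    chunk = max(1, int(2e7) // max(1, len(iu)))
    for start in range(0, values.shape[0], chunk):
        block = values[start:start + chunk]
        prod = (block[:, iu] - block[:, ju]) * grade_diff
        out[start:start + chunk] = (prod > 0).sum(axis=1) / n_pairs
    return out


def select_anchors(expr: ExpressionMatrix, grades: ResponseGrades,
                   threshold: float = 0.6, two_sided: bool = False) -> AnchorResult:
    """Compute C_g for every gene over the graded samples and select anchors.

    Anchors are genes with C_g strictly greater than ``threshold``; with
    ``two_sided=True`` genes with C_g < 1 - threshold (anti-consistent) are
    added as well. Result is sorted by descending C_g, ties broken by gene
    symbol.
    """
    if not 0.5 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0.5, 1], got {threshold}")
    missing = [s for s in grades.samples if s not in expr.samples]
    if missing:
        raise ValidationError(f"graded samples absent from expression matrix: {missing}")
    if len(np.unique(grades.grades)) < 2:
        raise ValidationError("need at least 2 distinct response grades")
    sub = expr.subset(samples=grades.samples)
    cvals = _consistency_matrix(sub.values, grades.grades)
    order = sorted(range(len(sub.genes)), key=lambda i: (-cvals[i], sub.genes[i]))
    consistency = pd.Series(cvals[order], index=[sub.genes[i] for i in order],
                            name="consistency")
    anchors = [g for g, c in consistency.items() if c > threshold]
    if two_sided:
        anchors += [g for g, c in consistency.items() if c < 1 - threshold]
    if not anchors:
        logger.warning("no gene exceeded the consistency threshold %.3f", threshold)
    return AnchorResult(consistency, threshold, anchors)
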