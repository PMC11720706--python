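"""Readers, writers and light preprocessing for the on-disk formats.

Expression matrices are genes-as-rows TSV (the common transcriptomics layout),
clinical tables are sample/time/event(/response) TSV, protein interactions use
the STRING ``protein-links`` layout, and gene sets use GMT. Every reader
validates domain invariants up front so downstream stages can assume clean
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

RESPONSE_LABELS = ("CR", "PR", "SD", "PD")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "RESPONSE_LABELS",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_string_edges",
    "write_string_edges",
    "read_gmt",
    "write_gmt",
    "log_transform",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix.

    Parameters
    ----------
    genes, samples
        Unique identifiers for rows and columns, order-preserving.
    values
        Real matrix of shape ``(len(genes), len(samples))``. Units are TPM
        (``scale_tag="tpm"``) or log2(TPM+1) (``scale_tag="log2"``).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in ("tpm", "log2"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.scale_tag == "tpm" and np.any(self.values < 0):
            raise ValidationError("TPM expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def gene_row(self, gene: str) -> np.ndarray:
        """Expression of one gene across all samples."""
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given genes/samples, in the given order."""
        frame = self.to_frame()
        if genes is not None:
            missing = [g for g in genes if g not in frame.index]
            if missing:
                raise KeyError(f"genes not in matrix: {missing}")
            frame = frame.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in frame.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing}")
            frame = frame[list(samples)]
        return ExpressionMatrix(list(frame.index), list(frame.columns),
                                frame.to_numpy(), self.scale_tag)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome with an optional immunotherapy response label."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"sample", "time", "event"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        if df["sample"].duplicated().any():
            dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        df["time"] = pd.to_numeric(df["time"])
        df["event"] = pd.to_numeric(df["event"])
        if (df["time"] <= 0).any():
            bad = df.loc[df["time"] <= 0, "sample"].tolist()
            raise ValidationError(f"non-positive survival times for samples: {bad}")
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "sample"].tolist()
            raise ValidationError(f"event indicator must be 0/1; offending samples: {bad}")
        if "response" in df.columns:
            labelled = df["response"].notna()
            bad_mask = labelled & ~df["response"].isin(RESPONSE_LABELS)
            if bad_mask.any():
                raise ValidationError(
                    f"response labels outside {RESPONSE_LABELS}: "
                    f"{sorted(df.loc[bad_mask, 'response'].unique())}"
                )
        else:
            df["response"] = pd.NA
        self.data = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.data["sample"].tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def response(self) -> pd.Series:
        return self.data.set_index("sample")["response"]

    def graded(self) -> "ClinicalTable":
        """Rows that carry an mRECIST response label."""
        return ClinicalTable(self.data[self.data["response"].notna()].copy())

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        df = self.data.set_index("sample").loc[list(samples)].reset_index()
        return ClinicalTable(df)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen.add(x)
    if dupes:
        raise FormatError(f"duplicate {kind} IDs: {sorted(set(dupes))}")


def read_expression(path: str | Path, scale_tag: str = "log2",
                    transpose: bool = False) -> ExpressionMatrix:
    """Read a genes-as-rows expression TSV (first column gene symbols, header sample IDs).

    Set ``transpose=True`` for samples-as-rows files.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        raise FormatError(
            f"non-numeric expression values in column {col!r}, rows {bad_rows[:5]}"
        )
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns],
        df.to_numpy(dtype=float), scale_tag,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample/time/event and optional response."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    known = {"sample", "time", "event", "response"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.info("ignoring extra clinical columns: %s", extra)
        df = df[[c for c in df.columns if c in known]]
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data
    if df["response"].isna().all():
        df = df.drop(columns=["response"])
    df.to_csv(path, sep="\t", index=False)


def read_string_edges(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a STRING protein-links file into undirected (node, node, score) records.

    Columns are located by header name (protein1/protein2/combined_score, any
    order, tab- or whitespace-delimited). The two orientations of an edge are
    collapsed keeping the maximum combined score.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    try:
        p1, p2, sc = cols["protein1"], cols["protein2"], cols["combined_score"]
    except KeyError as exc:
        raise FormatError(f"STRING links file missing column {exc.args[0]!r}") from None
    scores = pd.to_numeric(df[sc])
    if (scores < 0).any() or (scores > 1000).any():
        raise ValidationError("combined_score values must lie in [0, 1000]")
    best: dict[tuple[str, str], int] = {}
    for a, b, s in zip(df[p1].astype(str), df[p2].astype(str), scores.astype(int)):
        key = (a, b) if a <= b else (b, a)
        if s > best.get(key, -1):
            best[key] = s
    return [(a, b, s) for (a, b), s in best.items()]


def write_string_edges(edges: Sequence[tuple[str, str, int]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered ``{set name: gene list}`` mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and at least one gene"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) variance-stabilising transform of a TPM matrix."""
    if expr.scale_tag == "log2":
        raise ValidationError("matrix is already log2-scaled; refusing to transform twice")
    return ExpressionMatrix(expr.genes, expr.samples,
                            np.log2(expr.values + 1.0), "log2")
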