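"""Matrix, annotation and report I/O plus the shared domain containers.

Expression matrices travel as delimited text (first column gene id, header
row of sample ids); annotation tables as three-column TSV; reports as
schema-versioned JSON or flat CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_CATEGORIES = ("symbol", "cdna", "hypothetical", "non_human", "obsolete")


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent identifiers."""


class DomainError(ValueError):
    """Values outside the permitted domain (e.g. negative intensities)."""


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples matrix with ids and condition labels."""

    values: np.ndarray = field(repr=False)
    gene_ids: list[str]
    sample_ids: list[str]
    condition_labels: Optional[list[str]] = None
    scale: str = "linear"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise IntegrityError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m:
            raise IntegrityError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if len(set(self.gene_ids)) != n:
            raise IntegrityError("duplicate gene ids")
        if len(set(self.sample_ids)) != m:
            raise IntegrityError("duplicate sample ids")
        if self.condition_labels is not None:
            self.condition_labels = [str(c) for c in self.condition_labels]
            if len(self.condition_labels) != m:
                raise IntegrityError("condition_labels length does not match samples")
        if self.scale not in ("linear", "log2-display-only"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None


@dataclass
class GeneAnnotation:
    """Per-probe symbol (when present) and category.

    ``categories[probe]`` is one of :data:`ANNOTATION_CATEGORIES`;
    ``symbols[probe]`` is a string iff the category is "symbol".
    """

    symbols: dict[str, Optional[str]]
    categories: dict[str, str]

    def __post_init__(self):
        if set(self.symbols) != set(self.categories):
            raise IntegrityError("symbol and category tables cover different probes")
        for probe, cat in self.categories.items():
            if cat not in ANNOTATION_CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for probe {probe!r}")
            has_symbol = self.symbols[probe] is not None
            if has_symbol != (cat == "symbol"):
                raise IntegrityError(
                    f"probe {probe!r}: symbol presence inconsistent with category {cat!r}"
                )

    @property
    def probes(self) -> list[str]:
        return list(self.categories)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in ANNOTATION_CATEGORIES}
        for cat in self.categories.values():
            counts[cat] += 1
        return counts


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(
    path,
    clamp_negatives: bool = True,
    condition_labels=None,
) -> ExpressionMatrix:
    """Read a delimited genes x samples table (first column gene id).

    Negative entries are clamped to 0 (with a logged count) unless
    ``clamp_negatives`` is False, in which case they raise ``DomainError``.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise IntegrityError(f"duplicate gene id {dup!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"non-numeric cell at gene {row!r}, sample {col!r} in {path}")
        df[col] = coerced
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"missing cell at gene {df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    n_neg = int((values < 0).sum())
    if n_neg:
        if not clamp_negatives:
            raise DomainError(f"{n_neg} negative entries in {path} and clamping disabled")
        logger.warning("clamped %d negative entries to 0 while reading %s", n_neg, path)
        values = np.clip(values, 0.0, None)
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(c) for c in df.columns],
        condition_labels=condition_labels,
    )


def write_expression(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_annotation(path) -> GeneAnnotation:
    """Read a probe_id / symbol / category TSV written by :func:`write_annotation`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    symbols: dict[str, Optional[str]] = {}
    categories: dict[str, str] = {}
    for probe, symbol, cat in zip(df["probe_id"], df["symbol"], df["category"]):
        if probe in categories:
            raise IntegrityError(f"duplicate probe id {probe!r} in {path}")
        categories[probe] = cat
        symbols[probe] = symbol if cat == "symbol" else None
    return GeneAnnotation(symbols=symbols, categories=categories)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    rows = [
        {
            "probe_id": probe,
            "symbol": annotation.symbols[probe] or "",
            "category": annotation.categories[probe],
        }
        for probe in annotation.probes
    ]
    pd.DataFrame(rows, columns=["probe_id", "symbol", "category"]).to_csv(
        path, sep="\t", index=False
    )


def log2_display_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """log2(x + pseudocount), display/export only — never fed to the NMF."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if matrix.scale != "linear":
        raise ValueError("input matrix must be linear-scale")
    return np.log2(matrix.values + pseudocount)


def write_report(report, path, format: str = "json") -> None:
    """Serialize a report object (any object exposing to_dict / to_frame).

    JSON output is schema-versioned and lossless for objects with
    ``to_dict``; CSV output uses ``to_frame`` and orders gene rows by
    descending score then id where a score column is present.
    """
    path = Path(path)
    if format == "json":
        if not hasattr(report, "to_dict"):
            raise TypeError(f"{type(report).__name__} has no JSON representation")
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        if not hasattr(report, "to_frame"):
            raise TypeError(f"{type(report).__name__} has no tabular representation")
        df = report.to_frame()
        if "score" in df.columns and "gene_id" in df.columns:
            df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                                kind="mergesort")
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_json_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path) -> dict:
    """Load a JSON config file mirroring the CLI flags (CLI overrides it)."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a JSON object")
    return cfg


def read_series_matrix(path, clamp_negatives: bool = True) -> ExpressionMatrix:
    """Convenience reader for GEO series-matrix text files.

    Parses the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``.  Provided for integrating the original GEO
    deposit; nothing in the pipeline depends on it.
    """
    rows = []
    header = None
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None or not rows:
        raise ParseError(f"no series-matrix table found in {path}")
    gene_ids = [r[0] for r in rows]
    try:
        values = np.array([[float(v) if v else np.nan for v in r[1:]] for r in rows])
    except ValueError as exc:
        raise ParseError(f"non-numeric cell in series-matrix table: {exc}") from exc
    values = np.where(np.isnan(values), 0.0, values)
    n_neg = int((values < 0).sum())
    if n_neg:
        if not clamp_negatives:
            raise DomainError(f"{n_neg} negative entries and clamping disabled")
        logger.warning("clamped %d negative entries from series matrix", n_neg)
        values = np.clip(values, 0.0, None)
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=header[1:])
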