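"""Common/uncommon gene-set comparison, annotation filtering and medians.

Given the extracted gene sets of two conditions, compute their intersection
and differences, map probes to symbols while counting the non-informative
annotation categories (cDNA, hypothetical protein, non-human, obsolete),
deduplicate symbols, and attach per-condition expression medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ANNOTATION_CATEGORIES, ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class ComparisonReport:
    """Common/uncommon sets with annotation accounting and medians."""

    common: list[str]
    only_a: list[str]
    only_b: list[str]
    category_counts: dict[str, dict[str, int]]
    symbol_lists: dict[str, list[str]]
    medians: dict[str, dict[str, float]]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "type": "ComparisonReport",
            "common": list(self.common),
            "only_a": list(self.only_a),
            "only_b": list(self.only_b),
            "category_counts": self.category_counts,
            "symbol_lists": self.symbol_lists,
            "medians": self.medians,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        return cls(
            common=list(d["common"]),
            only_a=list(d["only_a"]),
            only_b=list(d["only_b"]),
            category_counts={
                s: {c: int(v) for c, v in counts.items()}
                for s, counts in d["category_counts"].items()
            },
            symbol_lists={s: list(v) for s, v in d["symbol_lists"].items()},
            medians={g: {k: float(v) for k, v in m.items()} for g, m in d["medians"].items()},
            provenance=dict(d.get("provenance", {})),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for set_name, genes in (("common", self.common), ("only_a", self.only_a),
                                ("only_b", self.only_b)):
            for g in genes:
                med = self.medians.get(g, {})
                rows.append(
                    {
                        "gene_id": g,
                        "set": set_name,
                        "median_a": med.get("median_a", np.nan),
                        "median_b": med.get("median_b", np.nan),
                    }
                )
        return pd.DataFrame(rows, columns=["gene_id", "set", "median_a", "median_b"])


def compare_gene_sets(set_a, set_b) -> tuple[list[str], list[str], list[str]]:
    """Exact set algebra; each list is sorted lexicographically."""
    a, b = set(set_a), set(set_b)
    return sorted(a & b), sorted(a - b), sorted(b - a)


def annotate_and_filter(gene_set, annotation: GeneAnnotation):
    """Map probes to symbols and count the dropped categories.

    Probes missing from the annotation count as obsolete (logged).  The
    returned symbol list is deduplicated keeping the first occurrence in the
    deterministic input order (lists are taken as given; sets are sorted).
    """
    genes = list(gene_set) if not isinstance(gene_set, (set, frozenset)) else sorted(gene_set)
    counts = {c: 0 for c in ANNOTATION_CATEGORIES}
    symbols: list[str] = []
    seen: set[str] = set()
    for g in genes:
        cat = annotation.categories.get(g)
        if cat is None:
            logger.warning("probe %r missing from annotation: treated as obsolete", g)
            cat = "obsolete"
        counts[cat] += 1
        if cat == "symbol":
            sym = annotation.symbols[g]
            if sym not in seen:
                seen.add(sym)
                symbols.append(sym)
    return symbols, counts


def condition_medians(
    X_a: ExpressionMatrix, X_b: ExpressionMatrix, genes
) -> dict[str, dict[str, float]]:
    """Per-gene sample medians within each condition (numpy midpoint median)."""
    index_a = {g: i for i, g in enumerate(X_a.gene_ids)}
    index_b = {g: i for i, g in enumerate(X_b.gene_ids)}
    out: dict[str, dict[str, float]] = {}
    for g in genes:
        if g not in index_a or g not in index_b:
            raise KeyError(f"unknown gene id: {g!r}")
        out[g] = {
            "median_a": float(np.median(X_a.values[index_a[g]])),
            "median_b": float(np.median(X_b.values[index_b[g]])),
        }
    return out


def build_comparison_report(
    set_a,
    set_b,
    annotation: GeneAnnotation,
    X_a: ExpressionMatrix,
    X_b: ExpressionMatrix,
) -> ComparisonReport:
    """Full post-processing: set algebra, per-set annotation accounting,
    symbol deduplication and per-condition medians."""
    common, only_a, only_b = compare_gene_sets(set_a, set_b)
    category_counts = {}
    symbol_lists = {}
    for name, genes in (("common", common), ("only_a", only_a), ("only_b", only_b)):
        symbols, counts = annotate_and_filter(genes, annotation)
        category_counts[name] = counts
        symbol_lists[name] = symbols
    medians = condition_medians(X_a, X_b, common + only_a + only_b)
    return ComparisonReport(
        common=common,
        only_a=only_a,
        only_b=only_b,
        category_counts=category_counts,
        symbol_lists=symbol_lists,
        medians=medians,
        provenance={"n_set_a": len(set(set_a)), "n_set_b": len(set(set_b))},
    )
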