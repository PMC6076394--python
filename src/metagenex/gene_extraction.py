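"""Entropy-based gene scoring on the NMF basis matrix and gene selection.

A gene's score measures how concentrated its basis-matrix row is on a single
metagene (1 = one-hot, 0 = uniform).  Genes are selected when their score
strictly exceeds median + 3*MAD of all scores AND their row maximum strictly
exceeds the median of all entries of W.  Selected genes are assigned to their
argmax metagene and the metagene with the most selected genes is the
"most informative" one, whose gene list is the extracted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_nonneg_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be a 2-D matrix")
    if W.size and float(W.min()) < 0.0:
        raise ValueError("W contains negative entries")
    return W


@dataclass
class GeneScoreTable:
    """Per-gene scores, gate values and selection flags for one basis matrix.

    ``table`` has columns gene_id, score, row_max, argmax_metagene (1-based),
    selected; rows follow the input gene order.  ``threshold`` is
    median + 3*MAD of the scores (MAD unscaled) and ``w_median`` the median of
    all W entries; both selection gates are strict inequalities.
    """

    table: pd.DataFrame = field(repr=False)
    threshold: float
    w_median: float

    @property
    def selected_ids(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel["gene_id"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "type": "GeneScoreTable",
            "threshold": self.threshold,
            "w_median": self.w_median,
            "genes": self.table.to_dict(orient="records"),
        }


@dataclass
class MetageneGeneSets:
    """Selected genes partitioned by metagene, plus the most informative one.

    Gene lists are ordered by descending score then gene id.  Ties in both
    the per-gene argmax and the per-metagene count are broken by the lowest
    metagene index (1-based).
    """

    genes_by_metagene: dict[int, list[str]]
    most_informative: int

    @property
    def extracted_set(self) -> list[str]:
        return list(self.genes_by_metagene[self.most_informative])

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "type": "MetageneGeneSets",
            "genes_by_metagene": {str(k): v for k, v in self.genes_by_metagene.items()},
            "most_informative": self.most_informative,
            "tie_break": "lowest metagene index",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetageneGeneSets":
        return cls(
            genes_by_metagene={int(k): list(v) for k, v in d["genes_by_metagene"].items()},
            most_informative=int(d["most_informative"]),
        )


def gene_scores(W) -> np.ndarray:
    """Entropy-based concentration score in [0, 1] for each row of W.

    With p(i, k) = W[i, k] / sum_k W[i, k]:

        score(i) = 1 + (1 / log2 r) * sum_k p(i, k) * log2 p(i, k)

    using 0*log(0) = 0.  One-hot rows score 1, uniform rows 0.  All-zero rows
    score 0 (p undefined there).  For r = 1 nonzero rows score 1 by
    definition.
    """
    W = _as_nonneg_matrix(W)
    n, r = W.shape
    scores = np.zeros(n)
    rowsum = W.sum(axis=1)
    nz = rowsum > 0
    if r == 1:
        scores[nz] = 1.0
        return scores
    P = W[nz] / rowsum[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(np.maximum(P, 1e-300)), 0.0)
    scores[nz] = 1.0 + plogp.sum(axis=1) / np.log2(r)
    return np.clip(scores, 0.0, 1.0)


def selection_threshold(scores) -> float:
    """median(scores) + 3 * MAD(scores), with MAD unscaled."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    med = float(np.median(s))
    mad = float(np.median(np.abs(s - med)))
    return med + 3.0 * mad


def select_genes(W, gene_ids=None, scores=None) -> GeneScoreTable:
    """Apply the two-gate selection rule to every row of W.

    A gene is selected iff score > median + 3*MAD of all scores (strict) and
    its row maximum > median of all W entries (strict).
    """
    W = _as_nonneg_matrix(W)
    n = W.shape[0]
    if gene_ids is None:
        gene_ids = [f"G{i:06d}" for i in range(n)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n:
        raise ValueError(f"gene_ids length {len(gene_ids)} != {n} rows of W")
    if scores is None:
        scores = gene_scores(W)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n,):
        raise ValueError("scores must align with the rows of W")
    threshold = selection_threshold(scores)
    w_median = float(np.median(W))
    row_max = W.max(axis=1)
    selected = (scores > threshold) & (row_max > w_median)
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "score": scores,
            "row_max": row_max,
            "argmax_metagene": W.argmax(axis=1) + 1,
            "selected": selected,
        }
    )
    return GeneScoreTable(table=table, threshold=threshold, w_median=w_median)


def assign_and_pick(W, table: GeneScoreTable) -> MetageneGeneSets:
    """Assign selected genes to their argmax metagene and pick the largest.

    The most informative metagene is the one with the most selected genes;
    its gene list is the extracted set.  All ties resolve to the lowest
    metagene index.
    """
    W = _as_nonneg_matrix(W)
    r = W.shape[1]
    df = table.table
    if len(df) != W.shape[0]:
        raise ValueError("score table does not match the rows of W")
    sel = df[df["selected"]].sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    genes_by_metagene: dict[int, list[str]] = {k: [] for k in range(1, r + 1)}
    for gid, k in zip(sel["gene_id"], sel["argmax_metagene"]):
        genes_by_metagene[int(k)].append(gid)
    counts = np.array([len(genes_by_metagene[k]) for k in range(1, r + 1)])
    most = int(np.argmax(counts)) + 1
    return MetageneGeneSets(genes_by_metagene=genes_by_metagene, most_informative=most)
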