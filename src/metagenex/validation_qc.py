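"""QC statistics and the concatenated-matrix validation stage.

Covers per-gene volcano statistics (two-sample t per row), the first
principal component of the centered matrix, concatenation of the two
condition matrices, the concatenation rank bound, column-normalized metagene
sample weights, a per-condition weight summary with an exact rank-sum test,
and containment of a previously extracted gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, IntegrityError

logger = logging.getLogger(__name__)


@dataclass
class WeightSummary:
    """Per-sample weights of one metagene summarized by condition."""

    weights: dict[str, float]
    mean_weight: dict[str, float]
    top_counts: dict[str, int]
    rank_sum_statistic: float
    rank_sum_p: float
    containment: float | None = None
    selected_metagene: int | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "type": "WeightSummary",
            "weights": self.weights,
            "mean_weight": self.mean_weight,
            "top_counts": self.top_counts,
            "rank_sum_statistic": self.rank_sum_statistic,
            "rank_sum_p": self.rank_sum_p,
            "containment": self.containment,
            "selected_metagene": self.selected_metagene,
        }


def volcano_stats(X: ExpressionMatrix, labels=None, welch: bool = False) -> pd.DataFrame:
    """Per-gene two-sample t-test between the two label groups.

    Returns columns mean_diff (second-group mean minus first-group mean,
    groups ordered lexicographically), t_stat, p_value and neg_log10_p.  Pooled
    variance by default; Welch with ``welch=True``.  Genes with zero variance
    in both groups get t = 0, p = 1 by convention (logged).
    """
    if labels is None:
        labels = X.condition_labels
    if labels is None:
        raise ValueError("labels are required (none stored on the matrix)")
    labels = [str(l) for l in labels]
    if len(labels) != X.n_samples:
        raise ValueError("labels length does not match the number of samples")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two label groups required, got {groups}")
    ga = np.array([l == groups[0] for l in labels])
    gb = ~ga
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    A = X.values[:, ga]
    B = X.values[:, gb]
    mean_diff = B.mean(axis=1) - A.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_value = stats.ttest_ind(B, A, axis=1, equal_var=not welch)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    if degenerate.any():
        logger.warning(
            "%d genes with zero variance in both groups: p = 1 by convention",
            int(degenerate.sum()),
        )
        t_stat = np.where(degenerate, 0.0, t_stat)
        p_value = np.where(degenerate, 1.0, p_value)
    p_value = np.clip(np.nan_to_num(p_value, nan=1.0), np.finfo(float).tiny, 1.0)
    t_stat = np.nan_to_num(t_stat, nan=0.0)
    return pd.DataFrame(
        {
            "gene_id": X.gene_ids,
            "mean_diff": mean_diff,
            "t_stat": t_stat,
            "p_value": p_value,
            "neg_log10_p": -np.log10(p_value),
        }
    )


def pca_first_component(X) -> tuple[np.ndarray, float]:
    """First principal component of the gene-centered matrix.

    Rows (genes) are centered across samples; the loading vector is the first
    left singular vector with its largest-magnitude entry made positive.
    Returns ``(loadings, variance_fraction)``.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    centered = values - values.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("matrix is constant per gene: first component undefined")
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    loading = U[:, 0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    variance_fraction = float(s[0] ** 2 / (s**2).sum())
    return loading, variance_fraction


def concatenate_conditions(X_a: ExpressionMatrix, X_b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two condition matrices sharing the same gene order."""
    if X_a.gene_ids != X_b.gene_ids:
        for i, (ga, gb) in enumerate(zip(X_a.gene_ids, X_b.gene_ids)):
            if ga != gb:
                raise IntegrityError(
                    f"gene id mismatch at row {i}: {ga!r} != {gb!r}"
                )
        raise IntegrityError(
            f"gene lists differ in length: {len(X_a.gene_ids)} vs {len(X_b.gene_ids)}"
        )
    labels_a = X_a.condition_labels or ["A"] * X_a.n_samples
    labels_b = X_b.condition_labels or ["B"] * X_b.n_samples
    return ExpressionMatrix(
        values=np.hstack([X_a.values, X_b.values]),
        gene_ids=list(X_a.gene_ids),
        sample_ids=list(X_a.sample_ids) + list(X_b.sample_ids),
        condition_labels=labels_a + labels_b,
    )


def rank_bound_check(r_concat: int, r_a: int, r_b: int) -> bool:
    """True iff the concatenation rank bound r_concat < r_a + r_b holds."""
    if min(r_concat, r_a, r_b) < 1:
        raise ValueError("ranks must be positive integers")
    return r_concat < r_a + r_b


def metagene_sample_weights(H, k: int) -> np.ndarray:
    """Column-normalized weight of metagene ``k`` (1-based) per sample."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be 2-D")
    if H.size and float(H.min()) < 0:
        raise ValueError("H contains negative entries")
    if not 1 <= k <= H.shape[0]:
        raise ValueError(f"metagene index {k} out of range 1..{H.shape[0]}")
    colsum = H.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"sample {int(zero[0])} has an all-zero coefficient column")
    return H[k - 1] / colsum


def group_weight_summary(
    weights,
    labels,
    top_is_selected=None,
    sample_ids=None,
) -> WeightSummary:
    """Summarize metagene weights by condition with an exact rank-sum test.

    ``top_is_selected`` is an optional per-sample boolean marking whether the
    sample's maximal-weight metagene is the selected one.  The rank-sum test
    is the two-sided Wilcoxon/Mann-Whitney test with the exact small-sample
    null (group-B weights versus group-A weights).
    """
    weights = np.asarray(weights, dtype=float)
    labels = [str(l) for l in labels]
    if len(labels) != weights.size:
        raise ValueError("labels length does not match weights")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two label groups required, got {groups}")
    ga = np.array([l == groups[0] for l in labels])
    wa, wb = weights[ga], weights[~ga]
    if np.ptp(weights) == 0:
        stat, p = float(len(wa) * len(wb) / 2), 1.0
    else:
        res = stats.mannwhitneyu(wb, wa, alternative="two-sided", method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(weights.size)]
    top_counts = {g: 0 for g in groups}
    if top_is_selected is not None:
        top_is_selected = np.asarray(top_is_selected, dtype=bool)
        for lab, top in zip(labels, top_is_selected):
            top_counts[lab] += int(top)
    return WeightSummary(
        weights={str(s): float(w) for s, w in zip(sample_ids, weights)},
        mean_weight={groups[0]: float(wa.mean()), groups[1]: float(wb.mean())},
        top_counts=top_counts,
        rank_sum_statistic=stat,
        rank_sum_p=min(p, 1.0),
    )


def containment(extracted_concat, common) -> float:
    """Fraction of ``common`` recovered in the concatenated extraction."""
    common = set(common)
    if not common:
        raise ValueError("common set must be non-empty")
    return len(common & set(extracted_concat)) / len(common)


def gini_coefficient(x) -> float:
    """Gini coefficient of a nonnegative vector (sparsity proxy)."""
    x = np.sort(np.abs(np.asarray(x, dtype=float)))
    n = x.size
    total = x.sum()
    if n == 0 or total == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float((2 * (i * x).sum()) / (n * total) - (n + 1) / n)
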