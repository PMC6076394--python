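"""Synthetic two-condition expression studies with planted metagene structure.

Marker genes of a factor receive a large basis loading on that factor and a
small baseline elsewhere; non-marker genes get i.i.d. uniform(0, baseline)
loadings.  Each sample is dominated by one factor (round-robin) so samples
cluster by factor, which is what consensus-based rank selection needs.
Noise is multiplicative-counting (Poisson, default) or additive truncated
Gaussian; noise_scale = 0 returns W @ H exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import ANNOTATION_CATEGORIES, ExpressionMatrix, GeneAnnotation

NOISE_MODELS = ("truncated-gaussian", "poisson")


@dataclass
class PlantedStudy:
    """Two-condition study with ground-truth factors and marker sets."""

    X_a: ExpressionMatrix
    X_b: ExpressionMatrix
    W_true_a: np.ndarray = field(repr=False)
    W_true_b: np.ndarray = field(repr=False)
    H_true_a: np.ndarray = field(repr=False)
    H_true_b: np.ndarray = field(repr=False)
    marker_sets_a: list[set[str]]
    marker_sets_b: list[set[str]]
    shared_markers: set[str]
    specific_markers_b: set[str]
    annotation: GeneAnnotation
    seed: int

    @property
    def dominant_markers_a(self) -> set[str]:
        return set(self.marker_sets_a[0])

    @property
    def dominant_markers_b(self) -> set[str]:
        return set(self.marker_sets_b[0])

    def truth_dict(self) -> dict:
        return {
            "schema_version": 1,
            "type": "PlantedStudyTruth",
            "seed": self.seed,
            "marker_sets_a": [sorted(s) for s in self.marker_sets_a],
            "marker_sets_b": [sorted(s) for s in self.marker_sets_b],
            "shared_markers": sorted(self.shared_markers),
            "specific_markers_b": sorted(self.specific_markers_b),
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2)
            fh.write("\n")


def _apply_noise(WH, noise_model, noise_scale, rng):
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise_model!r}")
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    if noise_scale == 0:
        return WH.copy()
    if noise_model == "truncated-gaussian":
        return np.clip(WH + noise_scale * rng.standard_normal(WH.shape), 0.0, None)
    # scaled Poisson: mean WH, variance noise_scale * WH
    return noise_scale * rng.poisson(WH / noise_scale).astype(float)


def _plant_basis(n_genes, rank, marker_index_sets, signal, baseline, background, rng):
    # markers: `signal` on their factor, `baseline` elsewhere; the rest flat
    W = rng.uniform(0.0, background, size=(n_genes, rank))
    for k, idx in enumerate(marker_index_sets):
        for i in idx:
            W[i, :] = baseline
            W[i, k] = signal
    return W


def _sample_coefficients(rank, n_samples, rng, dominant_low=0.8, dominant_high=1.2,
                         background=0.05, extra_to_dominant=False,
                         dominant_floor=None):
    # each sample dominated by one factor (round-robin); optionally the
    # leftover samples beyond the first `rank` all go to factor 0 so that one
    # factor dominates the condition, and factor 0 may get a small floor
    # weight in every sample of the condition
    H = rng.uniform(0.0, background, size=(rank, n_samples))
    for j in range(n_samples):
        k = 0 if (extra_to_dominant and j >= rank) else j % rank
        H[k, j] = rng.uniform(dominant_low, dominant_high)
    if dominant_floor is not None:
        lo, hi = dominant_floor
        H[0, :] = np.maximum(H[0, :], rng.uniform(lo, hi, size=n_samples))
    return H


def generate_planted_matrix(
    n_genes: int,
    n_samples: int,
    rank: int,
    markers_per_factor: int,
    signal: float = 10.0,
    baseline: float = 0.1,
    background: float | None = None,
    noise_model: str = "poisson",
    noise_scale: float = 1.0,
    seed: int = 0,
    gene_ids=None,
    sample_prefix: str = "S",
):
    """Single-condition planted matrix: X = clamp+(W_true @ H_true + noise).

    Returns ``(ExpressionMatrix, W_true, H_true, marker_sets)`` where
    ``marker_sets[k]`` is the set of gene ids planted on factor k.
    Deterministic given ``seed``.
    """
    if n_genes < 1 or n_samples < 1 or rank < 1:
        raise ValueError("dimensions and rank must be positive")
    if markers_per_factor < 0 or rank * markers_per_factor > n_genes:
        raise ValueError("rank * markers_per_factor must not exceed n_genes")
    if signal <= 0 or baseline <= 0:
        raise ValueError("signal and baseline must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    if gene_ids is None:
        gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    perm = rng.permutation(n_genes)
    marker_index_sets = [
        perm[k * markers_per_factor : (k + 1) * markers_per_factor]
        for k in range(rank)
    ]
    if background is None:
        background = baseline
    W = _plant_basis(n_genes, rank, marker_index_sets, signal, baseline, background, rng)
    H = _sample_coefficients(rank, n_samples, rng)
    X = _apply_noise(W @ H, noise_model, noise_scale, rng)
    matrix = ExpressionMatrix(
        values=X,
        gene_ids=gene_ids,
        sample_ids=[f"{sample_prefix}{j + 1}" for j in range(n_samples)],
    )
    marker_sets = [set(gene_ids[i] for i in idx) for idx in marker_index_sets]
    return matrix, W, H, marker_sets


def generate_annotation(
    gene_ids,
    frac_cdna: float = 0.0,
    frac_hypothetical: float = 0.0,
    frac_non_human: float = 0.0,
    frac_obsolete: float = 0.0,
    n_duplicate_symbols: int = 0,
    seed: int = 0,
) -> GeneAnnotation:
    """Annotation table with category fractions and planted duplicate symbols.

    Realized category counts are the rounded fractions of the probe count;
    the remainder is category "symbol" with a unique symbol per probe, except
    that exactly ``n_duplicate_symbols`` symbol probes are re-assigned the
    symbol of another (distinct) symbol probe.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    fracs = (frac_cdna, frac_hypothetical, frac_non_human, frac_obsolete)
    if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
        raise ValueError("category fractions must be nonnegative and sum to <= 1")
    counts = {
        "cdna": round(frac_cdna * n),
        "hypothetical": round(frac_hypothetical * n),
        "non_human": round(frac_non_human * n),
        "obsolete": round(frac_obsolete * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("rounded category counts exceed the number of probes")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    order = rng.permutation(n)
    categories: dict[str, str] = {}
    pos = 0
    for cat in ("cdna", "hypothetical", "non_human", "obsolete"):
        for i in order[pos : pos + counts[cat]]:
            categories[gene_ids[i]] = cat
        pos += counts[cat]
    symbol_probes = [gene_ids[i] for i in order[pos:]]
    for probe in symbol_probes:
        categories[probe] = "symbol"
    n_sym = len(symbol_probes)
    if n_duplicate_symbols < 0 or (n_duplicate_symbols and n_sym < 2 * n_duplicate_symbols):
        raise ValueError(
            f"cannot plant {n_duplicate_symbols} duplicate symbols among {n_sym} "
            "symbol probes"
        )
    symbols: dict[str, Optional[str]] = {p: None for p in gene_ids}
    for i, probe in enumerate(symbol_probes):
        symbols[probe] = f"SYM{i:05d}"
    if n_duplicate_symbols:
        pick = rng.choice(n_sym, size=2 * n_duplicate_symbols, replace=False)
        donors, copies = pick[:n_duplicate_symbols], pick[n_duplicate_symbols:]
        for d, c in zip(donors, copies):
            symbols[symbol_probes[c]] = symbols[symbol_probes[d]]
    # canonical probe order
    symbols = {p: symbols[p] for p in gene_ids}
    categories = {p: categories[p] for p in gene_ids}
    return GeneAnnotation(symbols=symbols, categories=categories)


def generate_two_condition_study(
    n_genes: int = 2000,
    m_a: int = 8,
    m_b: int = 10,
    rank_a: int = 5,
    rank_b: int = 8,
    shared_fraction: float = 0.1,
    markers_per_factor: int = 20,
    dominant_markers_a: int = 60,
    dominant_markers_b: int = 150,
    specific_off_level: float = 0.5,
    shared_level_a: float = 0.6,
    signal: float = 50.0,
    baseline: float = 0.5,
    background: float = 5.0,
    noise_model: str = "poisson",
    noise_scale: float = 1.0,
    frac_cdna: float = 0.05,
    frac_hypothetical: float = 0.02,
    frac_non_human: float = 0.02,
    frac_obsolete: float = 0.01,
    n_duplicate_symbols: int = 5,
    seed: int = 0,
) -> PlantedStudy:
    """Two-condition study whose condition-B dominant factor mixes shared and
    B-specific markers.

    Factor 1 of each condition carries the largest marker set, so it is the
    factor the downstream extraction should single out.  A fraction
    ``shared_fraction`` of condition B's dominant markers is drawn from
    condition A's dominant markers (the shared set); the rest are planted
    only in B (the B-specific set).  Condition B's dominant factor also
    carries an elevated background weight in every B sample, so its genes
    separate the two conditions in the concatenated matrix.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    if m_a < 1 or m_b < 1 or n_genes < 1:
        raise ValueError("dimensions must be positive")
    need = (
        dominant_markers_a
        + markers_per_factor * (rank_a - 1)
        + dominant_markers_b
        + markers_per_factor * (rank_b - 1)
    )
    if need > n_genes:
        raise ValueError(
            f"marker plan needs {need} genes but only {n_genes} are available"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    pool = list(rng.permutation(n_genes))

    def take(k):
        out, pool[:] = pool[:k], pool[k:]
        return out

    # condition A markers: dominant factor first, then the rest
    idx_a = [take(dominant_markers_a)]
    idx_a += [take(markers_per_factor) for _ in range(rank_a - 1)]

    n_shared = round(shared_fraction * dominant_markers_b)
    if n_shared > dominant_markers_a:
        raise ValueError(
            f"shared_fraction {shared_fraction} needs {n_shared} shared markers "
            f"but condition A's dominant factor has only {dominant_markers_a}"
        )
    shared_idx = list(rng.choice(idx_a[0], size=n_shared, replace=False)) if n_shared else []
    specific_idx = take(dominant_markers_b - n_shared)
    idx_b = [shared_idx + specific_idx]
    idx_b += [take(markers_per_factor) for _ in range(rank_b - 1)]

    W_a = _plant_basis(n_genes, rank_a, idx_a, signal, baseline, background, rng)
    W_b = _plant_basis(n_genes, rank_b, idx_b, signal, baseline, background, rng)
    # B-specific markers are essentially off in condition A, so the
    # concatenated fit's dominant-B metagene separates the conditions
    W_a[specific_idx, :] = rng.uniform(0.0, specific_off_level,
                                       size=(len(specific_idx), rank_a))
    # shared markers are expressed in both conditions but more strongly in
    # B, so the concatenated fit assigns them to the dominant-B metagene
    if shared_idx:
        W_a[shared_idx, 0] = signal * shared_level_a
    H_a = _sample_coefficients(rank_a, m_a, rng)
    H_b = _sample_coefficients(rank_b, m_b, rng, extra_to_dominant=True)
    X_a = _apply_noise(W_a @ H_a, noise_model, noise_scale, rng)
    X_b = _apply_noise(W_b @ H_b, noise_model, noise_scale, rng)

    annotation = generate_annotation(
        gene_ids,
        frac_cdna=frac_cdna,
        frac_hypothetical=frac_hypothetical,
        frac_non_human=frac_non_human,
        frac_obsolete=frac_obsolete,
        n_duplicate_symbols=n_duplicate_symbols,
        seed=seed,
    )
    return PlantedStudy(
        X_a=ExpressionMatrix(
            values=X_a,
            gene_ids=gene_ids,
            sample_ids=[f"A{j + 1}" for j in range(m_a)],
            condition_labels=["A"] * m_a,
        ),
        X_b=ExpressionMatrix(
            values=X_b,
            gene_ids=gene_ids,
            sample_ids=[f"B{j + 1}" for j in range(m_b)],
            condition_labels=["B"] * m_b,
        ),
        W_true_a=W_a,
        W_true_b=W_b,
        H_true_a=H_a,
        H_true_b=H_b,
        marker_sets_a=[set(gene_ids[i] for i in idx) for idx in idx_a],
        marker_sets_b=[set(gene_ids[i] for i in idx) for idx in idx_b],
        shared_markers=set(gene_ids[i] for i in shared_idx),
        specific_markers_b=set(gene_ids[i] for i in specific_idx),
        annotation=annotation,
        seed=seed,
    )
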