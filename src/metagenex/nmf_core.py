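"""Nonnegative matrix factorization under the generalized Kullback-Leibler divergence.

Implements the classic multiplicative update rules, multi-start fitting with a
best-of-``n_runs`` selection by final divergence, and empirical rank selection
via consensus clustering of sample assignments across random restarts together
with the cophenetic correlation of the consensus matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Floor applied to denominators and logarithm arguments.
EPS = 1e-12


def _as_nonneg(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.size and float(arr.min()) < 0.0:
        raise ValueError(f"{name} contains negative entries")
    return arr


def _check_shapes(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    if W.ndim != 2 or H.ndim != 2 or X.ndim != 2:
        raise ValueError("X, W and H must be 2-D arrays")
    if W.shape[1] != H.shape[0] or X.shape[0] != W.shape[0] or X.shape[1] != H.shape[1]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, W {W.shape}, H {H.shape}"
        )


@dataclass
class NMFModel:
    """Result of a multi-start KL-NMF fit.

    Attributes
    ----------
    W : basis matrix, shape (n_genes, rank), nonnegative.
    H : coefficient matrix, shape (rank, n_samples), nonnegative.
    divergence : final generalized KL divergence of the best run.
    n_iter : iterations performed by the best run.
    converged : whether the best run stopped on tolerance before ``max_iter``.
    seed : master seed of the multi-start schedule.
    divergence_trace : per-iteration divergence of the best run (including
        the initial value), non-increasing up to numerical slack.
    """

    W: np.ndarray
    H: np.ndarray
    divergence: float
    n_iter: int
    converged: bool
    seed: int
    divergence_trace: np.ndarray = field(repr=False)

    @property
    def rank(self) -> int:
        return self.W.shape[1]


@dataclass
class RankSurvey:
    """Per-rank consensus matrices and cophenetic coefficients.

    ``selected_rank`` follows the "largest rank before the first drop of the
    cophenetic coefficient below ``theta``" rule, falling back to the argmax
    of the cophenetic coefficients when no rank precedes such a drop.
    """

    ranks: list[int]
    consensus: dict[int, np.ndarray] = field(repr=False)
    cophenetic: dict[int, float]
    selected_rank: int
    theta: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "type": "RankSurvey",
            "ranks": list(self.ranks),
            "cophenetic": {str(r): self.cophenetic[r] for r in self.ranks},
            "consensus": {str(r): self.consensus[r].tolist() for r in self.ranks},
            "selected_rank": self.selected_rank,
            "theta": self.theta,
            "seed": self.seed,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": self.ranks,
                "cophenetic": [self.cophenetic[r] for r in self.ranks],
                "selected": [r == self.selected_rank for r in self.ranks],
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RankSurvey":
        ranks = [int(r) for r in d["ranks"]]
        return cls(
            ranks=ranks,
            consensus={r: np.asarray(d["consensus"][str(r)], dtype=float) for r in ranks},
            cophenetic={r: float(d["cophenetic"][str(r)]) for r in ranks},
            selected_rank=int(d["selected_rank"]),
            theta=float(d["theta"]),
            seed=int(d["seed"]),
        )


def kl_divergence(X, W, H) -> float:
    """Generalized KL divergence D(X || WH) = sum x*ln(x/y) - x + y.

    The convention 0*ln(0) = 0 applies and denominators are floored at
    :data:`EPS`.  Always >= 0, and 0 iff X == WH entrywise (within EPS).
    """
    X = _as_nonneg(X, "X")
    W = _as_nonneg(W, "W")
    H = _as_nonneg(H, "H")
    _check_shapes(X, W, H)
    WH = W @ H
    d = float(WH.sum() - X.sum())
    pos = X > 0
    if pos.any():
        ratio = np.maximum(X[pos] / np.maximum(WH[pos], EPS), 1e-300)
        d += float((X[pos] * np.log(ratio)).sum())
    return max(d, 0.0)


def multiplicative_update(X, W, H) -> tuple[np.ndarray, np.ndarray]:
    """One round of the KL multiplicative updates: H first, then W.

    Nonnegativity is preserved and the divergence is non-increasing up to
    numerical slack.
    """
    X = _as_nonneg(X, "X")
    W = np.array(W, dtype=float)
    H = np.array(H, dtype=float)
    _check_shapes(X, W, H)
    WH = np.maximum(W @ H, EPS)
    H = H * (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
    WH = np.maximum(W @ H, EPS)
    W = W * ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
    return W, H


def _init_factors(X: np.ndarray, rank: int, rng: np.random.Generator):
    # uniform(0,1) entries scaled by sqrt(mean(X)/rank) so E[WH] ~ mean(X)/4
    scale = np.sqrt(max(float(X.mean()), EPS) / rank)
    W = rng.uniform(0.0, 1.0, size=(X.shape[0], rank)) * scale
    H = rng.uniform(0.0, 1.0, size=(rank, X.shape[1])) * scale
    return W, H


def _fit_single(X, rank, max_iter, tol, rng):
    W, H = _init_factors(X, rank, rng)
    trace = [kl_divergence(X, W, H)]
    converged = False
    for _ in range(max_iter):
        W, H = multiplicative_update(X, W, H)
        d = kl_divergence(X, W, H)
        prev = trace[-1]
        trace.append(d)
        if tol > 0 and (prev - d) / max(prev, EPS) < tol:
            converged = True
            break
    return W, H, np.asarray(trace), converged


def fit_nmf(
    X,
    rank: int,
    n_runs: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFModel:
    """Multi-start KL-NMF: best of ``n_runs`` random initializations.

    Each run ``k`` draws its initialization from a deterministic seed derived
    from ``(seed, k)``; the run with the lowest final divergence wins (ties
    broken by run order).  A run stops when the relative divergence decrease
    falls below ``tol`` or after ``max_iter`` updates.
    """
    X = _as_nonneg(X, "X")
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rank > min(X.shape):
        warnings.warn(
            f"rank {rank} exceeds min(n, m) = {min(X.shape)}; the factorization "
            "is over-complete",
            stacklevel=2,
        )
    best = None
    for k in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
        W, H, trace, converged = _fit_single(X, rank, max_iter, tol, rng)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, converged)
    W, H, trace, converged = best
    return NMFModel(
        W=W,
        H=H,
        divergence=float(trace[-1]),
        n_iter=len(trace) - 1,
        converged=converged,
        seed=seed,
        divergence_trace=trace,
    )


def consensus_matrix(
    X,
    rank: int,
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> np.ndarray:
    """Sample co-clustering frequency over ``n_runs`` independent restarts.

    In each run, sample ``j`` is assigned to the metagene with the largest
    coefficient ``H[k, j]``; the consensus entry (j, j') is the fraction of
    runs assigning j and j' to the same metagene.  Symmetric, unit diagonal,
    entries in [0, 1].
    """
    X = _as_nonneg(X, "X")
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must have at least 2 samples")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    m = X.shape[1]
    C = np.zeros((m, m))
    for k in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rank, k)))
        _, H, _, _ = _fit_single(X, rank, max_iter, tol, rng)
        assign = H.argmax(axis=0)
        C += assign[:, None] == assign[None, :]
    C /= n_runs
    np.fill_diagonal(C, 1.0)
    return C


def cophenetic_coefficient(consensus) -> float:
    """Cophenetic correlation of the consensus matrix.

    Pearson correlation between the (1 - consensus) distances and the
    cophenetic distances induced by their average-linkage dendrogram.
    A constant distance matrix (including the single-pair m = 2 case) is
    reproduced exactly by the hierarchy, so 1 is returned by convention.
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] < 2:
        raise ValueError("consensus must be a square matrix of size >= 2")
    D = 1.0 - (C + C.T) / 2.0
    np.fill_diagonal(D, 0.0)
    cond = squareform(D, checks=False)
    if cond.size < 2 or np.ptp(cond) < 1e-15:
        logger.info("constant distance matrix: cophenetic coefficient 1 by convention")
        return 1.0
    Z = average(cond)
    c, _ = cophenet(Z, cond)
    if not np.isfinite(c):
        logger.info("degenerate cophenetic correlation: returning 1 by convention")
        return 1.0
    return float(np.clip(c, -1.0, 1.0))


def survey_ranks(
    X,
    ranks,
    n_runs: int = 20,
    seed: int = 0,
    theta: float = 0.95,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> RankSurvey:
    """Consensus survey over candidate ranks with empirical rank selection."""
    ranks = sorted(int(r) for r in ranks)
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if any(r < 2 for r in ranks):
        raise ValueError("each candidate rank must be >= 2")
    consensus: dict[int, np.ndarray] = {}
    coph: dict[int, float] = {}
    for r in ranks:
        consensus[r] = consensus_matrix(X, r, n_runs=n_runs, seed=seed,
                                        max_iter=max_iter, tol=tol)
        coph[r] = cophenetic_coefficient(consensus[r])
    values = [coph[r] for r in ranks]
    below = [i for i, c in enumerate(values) if c < theta]
    if below and below[0] > 0:
        selected = ranks[below[0] - 1]
    else:
        selected = ranks[int(np.argmax(values))]
    return RankSurvey(
        ranks=ranks,
        consensus=consensus,
        cophenetic=coph,
        selected_rank=selected,
        theta=theta,
        seed=seed,
    )
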