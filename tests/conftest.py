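import numpy as np
import pytest

from metagenex import ExpressionMatrix, generate_two_condition_study
from metagenex.synthetic_data import generate_planted_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study():
    """A fast, fully-recoverable two-condition study for integration tests."""
    return generate_two_condition_study(
        n_genes=500,
        m_a=8,
        m_b=10,
        rank_a=3,
        rank_b=4,
        markers_per_factor=15,
        dominant_markers_a=30,
        dominant_markers_b=50,
        seed=0,
    )


@pytest.fixture
def planted_rank2():
    """Noiseless rank-2 planted matrix (100 x 8)."""
    matrix, W, H, markers = generate_planted_matrix(
        100, 8, 2, 10, signal=10.0, baseline=0.1, noise_scale=0.0, seed=7
    )
    return matrix, W, H, markers


def make_matrix(values, gene_prefix="g", sample_prefix="s", labels=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"{gene_prefix}{i}" for i in range(n)],
        sample_ids=[f"{sample_prefix}{j}" for j in range(m)],
        condition_labels=labels,
    )
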