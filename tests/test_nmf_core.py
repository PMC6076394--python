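import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metagenex.nmf_core import (
    NMFModel,
    consensus_matrix,
    cophenetic_coefficient,
    fit_nmf,
    kl_divergence,
    multiplicative_update,
    survey_ranks,
)
from metagenex.synthetic_data import generate_planted_matrix


def random_factors(rng, n, m, r):
    return rng.uniform(0.1, 2.0, (n, r)), rng.uniform(0.1, 2.0, (r, m))


class TestKLDivergence:
    def test_exact_factorization_is_zero(self, rng):
        W, H = random_factors(rng, 6, 4, 2)
        assert kl_divergence(W @ H, W, H) == pytest.approx(0.0, abs=1e-9)

    def test_worked_value_overestimate(self):
        # 2*ln2 - 2 + 1
        assert kl_divergence([[2.0]], [[1.0]], [[1.0]]) == pytest.approx(
            2 * np.log(2) - 1, abs=1e-12
        )

    def test_worked_value_underestimate(self):
        # ln(1/2) - 1 + 2
        assert kl_divergence([[1.0]], [[1.0]], [[2.0]]) == pytest.approx(
            np.log(0.5) + 1, abs=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            kl_divergence(np.ones((2, 2)), np.ones((2, 1)), np.ones((1, 3)))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kl_divergence([[-1.0]], [[1.0]], [[1.0]])

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            X = rng.uniform(0, 3, (5, 4))
            W, H = random_factors(rng, 5, 4, 2)
            assert kl_divergence(X, W, H) >= 0


class TestMultiplicativeUpdate:
    def test_fixed_point_at_exact_factorization(self, rng):
        W, H = random_factors(rng, 8, 5, 2)
        X = W @ H
        d0 = kl_divergence(X, W, H)
        W1, H1 = multiplicative_update(X, W, H)
        d1 = kl_divergence(X, W1, H1)
        assert d1 <= d0 + 1e-9 * (1 + d0)

    def test_monotone_divergence_200_steps(self, rng):
        X = rng.uniform(0, 5, (6, 4))
        W, H = random_factors(rng, 6, 4, 2)
        prev = kl_divergence(X, W, H)
        for _ in range(200):
            W, H = multiplicative_update(X, W, H)
            cur = kl_divergence(X, W, H)
            assert cur <= prev + 1e-9 * (1 + prev)
            prev = cur

    def test_zero_row_drives_basis_row_to_zero(self, rng):
        X = rng.uniform(1, 5, (6, 4))
        X[2] = 0.0
        W, H = random_factors(rng, 6, 4, 2)
        for _ in range(300):
            W, H = multiplicative_update(X, W, H)
        assert W[2].sum() < 1e-6

    def test_nonnegativity_preserved(self, rng):
        X = rng.uniform(0, 5, (7, 5))
        W, H = random_factors(rng, 7, 5, 3)
        for _ in range(50):
            W, H = multiplicative_update(X, W, H)
        assert (W >= 0).all() and (H >= 0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            multiplicative_update(np.ones((3, 3)), np.ones((3, 2)), np.ones((2, 2)))

    @given(
        X=arrays(
            np.float64,
            (5, 4),
            elements=st.floats(0, 10, allow_nan=False, allow_infinity=False),
        ),
        seed=st.integers(0, 2**31),
    )
    @settings(max_examples=30, deadline=None)
    def test_property_divergence_never_increases(self, X, seed):
        r = np.random.default_rng(seed)
        W, H = r.uniform(0.1, 1.0, (5, 2)), r.uniform(0.1, 1.0, (2, 4))
        prev = kl_divergence(X, W, H)
        for _ in range(20):
            W, H = multiplicative_update(X, W, H)
            cur = kl_divergence(X, W, H)
            assert cur <= prev + 1e-9 * (1 + prev)
            prev = cur


class TestFitNMF:
    def test_noiseless_planted_recovery(self, planted_rank2):
        matrix, W, H, _ = planted_rank2
        model = fit_nmf(matrix.values, rank=2, n_runs=10, max_iter=2000,
                        tol=1e-9, seed=3)
        assert model.divergence < 1e-6 * matrix.values.sum()

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(0, 5, (20, 6))
        m1 = fit_nmf(X, rank=2, n_runs=3, max_iter=50, tol=0.0, seed=11)
        m2 = fit_nmf(X, rank=2, n_runs=3, max_iter=50, tol=0.0, seed=11)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_higher_rank_fits_no_worse(self, rng):
        X = rng.uniform(0.5, 5, (30, 8))
        m2 = fit_nmf(X, rank=2, n_runs=5, max_iter=1500, tol=0.0, seed=5)
        m3 = fit_nmf(X, rank=3, n_runs=5, max_iter=1500, tol=0.0, seed=5)
        assert m3.divergence <= m2.divergence * (1 + 1e-6)

    def test_trace_monotone_and_final_value(self, rng):
        X = rng.uniform(0, 5, (15, 6))
        model = fit_nmf(X, rank=2, n_runs=2, max_iter=100, tol=0.0, seed=1)
        trace = model.divergence_trace
        assert model.divergence == trace[-1]
        slack = 1e-9 * (1 + trace[0])
        assert (np.diff(trace) <= slack).all()
        assert (model.W >= 0).all() and (model.H >= 0).all()

    def test_excessive_rank_warns(self, rng):
        X = rng.uniform(0.5, 2, (4, 3))
        with pytest.warns(UserWarning, match="rank"):
            fit_nmf(X, rank=5, n_runs=1, max_iter=10, tol=0.0, seed=0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_nmf(np.empty((0, 0)), rank=1)

    def test_invalid_rank_and_runs(self, rng):
        X = rng.uniform(0, 1, (4, 3))
        with pytest.raises(ValueError):
            fit_nmf(X, rank=0)
        with pytest.raises(ValueError):
            fit_nmf(X, rank=1, n_runs=0)

    def test_rank1_matches_closed_form_optimum(self, rng):
        # the best rank-1 KL fit is outer(rowsums, colsums) / total
        for _ in range(5):
            X = rng.uniform(0.2, 4.0, (6, 4))
            w = X.sum(axis=1, keepdims=True)
            h = X.sum(axis=0, keepdims=True) / X.sum()
            best = kl_divergence(X, w, h)
            model = fit_nmf(X, rank=1, n_runs=3, max_iter=2000, tol=0.0, seed=2)
            assert model.divergence <= best * 1.01 + 1e-12

    def test_scale_invariance_of_matched_iterates(self, rng):
        X = rng.uniform(0.5, 3, (8, 5))
        W, H = rng.uniform(0.1, 1, (8, 2)), rng.uniform(0.1, 1, (2, 5))
        c = 3.7
        Wc, Hc = W.copy(), c * H
        for _ in range(10):
            W, H = multiplicative_update(X, W, H)
            Wc, Hc = multiplicative_update(c * X, Wc, Hc)
        assert kl_divergence(c * X, Wc, Hc) == pytest.approx(
            c * kl_divergence(X, W, H), rel=1e-6
        )


def naive_average_linkage_cophenetic(D):
    """Brute-force average-linkage cophenetic correlation (first principles)."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def cdist(a, b):
        return np.mean([D[i, j] for i in a for j in b])

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = cdist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                coph[i, j] = coph[j, i] = d
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    iu = np.triu_indices(n, 1)
    a, b = D[iu], coph[iu]
    if a.std() == 0 or b.std() == 0:
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


@pytest.fixture(scope="module")
def separable():
    matrix, _, _, _ = generate_planted_matrix(
        60, 10, 2, 10, signal=20.0, baseline=0.1, noise_scale=0.0, seed=5
    )
    return matrix.values


class TestConsensusAndCophenetic:
    def test_consensus_shape_and_bounds(self, separable):
        C = consensus_matrix(separable, rank=2, n_runs=5, seed=0)
        assert C.shape == (10, 10)
        np.testing.assert_array_equal(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T)
        assert ((C >= 0) & (C <= 1)).all()

    def test_separable_consensus_is_binary(self, separable):
        C = consensus_matrix(separable, rank=2, n_runs=10, seed=0)
        assert np.isin(C, [0.0, 1.0]).all()

    def test_within_exceeds_between_cluster_consensus(self, separable):
        C = consensus_matrix(separable, rank=2, n_runs=20, seed=1)
        group = np.arange(10) % 2  # round-robin planted dominance
        same = group[:, None] == group[None, :]
        off_diag = ~np.eye(10, dtype=bool)
        assert C[same & off_diag].mean() > C[~same].mean()

    def test_consensus_validation(self, rng):
        with pytest.raises(ValueError):
            consensus_matrix(rng.uniform(0, 1, (5, 1)), rank=2, n_runs=5)
        with pytest.raises(ValueError):
            consensus_matrix(rng.uniform(0, 1, (5, 4)), rank=2, n_runs=1)

    def test_block_perfect_consensus_scores_one(self):
        C = np.kron(np.eye(3), np.ones((2, 2)))
        assert cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_two_sample_convention(self):
        assert cophenetic_coefficient(np.array([[1.0, 0.4], [0.4, 1.0]])) == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            C = np.kron(np.eye(2), np.ones((4, 4)))
            noise = rng.uniform(0, 0.3, (8, 8))
            noise = (noise + noise.T) / 2
            C = np.clip(C - noise, 0, 1)
            np.fill_diagonal(C, 1.0)
            D = 1 - C
            np.fill_diagonal(D, 0.0)
            expected = naive_average_linkage_cophenetic(D)
            assert cophenetic_coefficient(C) == pytest.approx(expected, abs=1e-10)
            assert cophenetic_coefficient(C) < 1.0


class TestSurveyRanks:
    def test_single_candidate_is_selected(self):
        matrix, _, _, _ = generate_planted_matrix(
            60, 8, 2, 10, noise_scale=0.0, seed=2
        )
        survey = survey_ranks(matrix.values, [3], n_runs=4, seed=0)
        assert survey.selected_rank == 3

    def test_deterministic(self):
        matrix, _, _, _ = generate_planted_matrix(80, 9, 3, 8, seed=4)
        s1 = survey_ranks(matrix.values, [2, 3], n_runs=4, seed=9)
        s2 = survey_ranks(matrix.values, [2, 3], n_runs=4, seed=9)
        assert s1.cophenetic == s2.cophenetic
        assert s1.selected_rank == s2.selected_rank
        for r in s1.ranks:
            np.testing.assert_array_equal(s1.consensus[r], s2.consensus[r])

    def test_planted_rank_recovered(self):
        matrix, _, _, _ = generate_planted_matrix(
            120, 20, 3, 15, signal=10.0, baseline=0.1, noise_scale=1.0, seed=0
        )
        survey = survey_ranks(matrix.values, range(2, 7), n_runs=20, seed=0)
        assert survey.selected_rank == 3

    def test_invalid_ranks_rejected(self, rng):
        X = rng.uniform(0, 1, (10, 5))
        with pytest.raises(ValueError):
            survey_ranks(X, [])
        with pytest.raises(ValueError):
            survey_ranks(X, [1, 2])

    def test_round_trip_dict(self):
        matrix, _, _, _ = generate_planted_matrix(50, 6, 2, 8, seed=3)
        s1 = survey_ranks(matrix.values, [2, 3], n_runs=3, seed=1)
        from metagenex.nmf_core import RankSurvey

        s2 = RankSurvey.from_dict(s1.to_dict())
        assert s2.selected_rank == s1.selected_rank
        assert s2.cophenetic == s1.cophenetic
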