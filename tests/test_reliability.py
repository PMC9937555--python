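import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structest.data_model import IndicatorMatrix, standardize
from structest.reliability import (
    CovarianceSet,
    EstimationError,
    IdentificationError,
    closed_form_d3,
    estimate_reliabilities,
    pairwise_covariances,
    reliability_jacobian,
    reliability_moment_rows,
    reliability_moment_vector,
    solve_from_covariances,
)
from structest.synthetic_data import GeneratorConfig, generate_null_dataset


class TestPairwiseCovariances:
    def test_hand_arithmetic_divisor_n(self):
        X = IndicatorMatrix(np.column_stack([[1.0, -1, 0, 0], [2.0, 0, -2, 0]]))
        C = pairwise_covariances(X).C
        assert C[0, 1] == pytest.approx(0.5)

    def test_identical_unit_variance_columns(self, rng):
        col = rng.standard_normal(100)
        col = (col - col.mean()) / col.std()
        X = IndicatorMatrix(np.column_stack([col, col]))
        assert pairwise_covariances(X).C[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        X = IndicatorMatrix(rng.standard_normal((100_000, 2)))
        assert abs(pairwise_covariances(X).C[0, 1]) < 0.02


class TestMomentVector:
    def test_hand_arithmetic(self):
        v = reliability_moment_vector(
            np.array([0.5, 0.2, -0.1]), np.zeros(3), np.array([0.8, 0.7, 0.6])
        )
        assert v[0] == pytest.approx(-0.640)

    def test_exact_fit_gives_zero(self):
        lam = np.array([0.8, 0.5, 0.4])
        # centered row with products (x_i)(x_j) = lam_i lam_j for all pairs
        x = lam.copy()
        assert np.allclose(
            reliability_moment_vector(x, np.zeros(3), lam), 0, atol=1e-12
        )

    def test_mean_zero_at_solution(self, prepared_p2):
        X, _ = prepared_p2
        est = estimate_reliabilities(X)
        V = reliability_moment_rows(X.values, X.values.mean(axis=0), est.lambda_)
        assert np.abs(V.mean(axis=0)).max() < 1e-8

    def test_unbiased_at_true_lambda(self):
        lam = np.array([0.8, 0.7, 0.75, 0.65, 0.6])
        data = generate_null_dataset(GeneratorConfig(d=5, N=50_000, p=2, seed=9))
        V = reliability_moment_rows(
            data.X.values, data.X.values.mean(axis=0), lam
        )
        mean = V.mean(axis=0)
        se = V.std(axis=0) / np.sqrt(V.shape[0])
        assert np.all(np.abs(mean) < 3 * se + 1e-3)


class TestEstimateReliabilities:
    def test_closed_form_triple(self):
        C = np.array([[1.0, 0.56, 0.48], [0.56, 1, 0.42], [0.48, 0.42, 1]])
        est = solve_from_covariances(CovarianceSet(C))
        assert np.allclose(est.lambda_, [0.8, 0.7, 0.6], atol=1e-8)

    @pytest.mark.parametrize("d", [3, 4, 6])
    def test_symmetric_case(self, d):
        C = np.full((d, d), 0.49)
        np.fill_diagonal(C, 1.0)
        est = solve_from_covariances(CovarianceSet(C))
        assert np.allclose(est.lambda_, 0.7, atol=1e-8)

    def test_parameter_recovery(self):
        lam = np.array([0.8, 0.7, 0.75, 0.65, 0.6])
        data = generate_null_dataset(GeneratorConfig(d=5, N=5000, p=2, seed=17))
        est = estimate_reliabilities(standardize(data.X))
        assert np.abs(est.lambda_ - lam).max() < 0.05

    def test_underidentified_d2(self, rng):
        X = IndicatorMatrix(rng.standard_normal((50, 2)))
        with pytest.raises(IdentificationError):
            estimate_reliabilities(X)

    def test_negative_covariance_names_pair(self):
        C = np.array([[1.0, 0.5, -0.3], [0.5, 1, 0.4], [-0.3, 0.4, 1]])
        with pytest.raises(EstimationError, match=r"C\[1,3\]"):
            solve_from_covariances(CovarianceSet(C))

    @given(
        st.tuples(
            st.floats(0.2, 0.95), st.floats(0.2, 0.95), st.floats(0.2, 0.95)
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_on_rank1_triples(self, lam):
        lam = np.asarray(lam)
        C = np.outer(lam, lam)
        np.fill_diagonal(C, 1.0)
        est = solve_from_covariances(CovarianceSet(C))
        assert np.allclose(est.lambda_, closed_form_d3(C), atol=1e-8)

    @given(st.integers(0, 10_000), st.integers(3, 6))
    @settings(max_examples=40, deadline=None)
    def test_solver_equivalence(self, seed, d):
        rng_ = np.random.default_rng(seed)
        lam = rng_.uniform(0.3, 0.9, d)
        noise = rng_.normal(0, 0.02, (d, d))
        C = np.outer(lam, lam) + (noise + noise.T) / 2
        np.fill_diagonal(C, 1.0)
        if np.any(C[~np.eye(d, dtype=bool)] <= 0.01):
            return
        a = solve_from_covariances(CovarianceSet(C), "root").lambda_
        b = solve_from_covariances(CovarianceSet(C), "quasi-poisson").lambda_
        assert np.abs(a - b).max() < 1e-6

    def test_consistency_large_n(self):
        lam = np.array([0.8, 0.7, 0.75, 0.65, 0.6])
        errs = []
        for s in range(10):
            data = generate_null_dataset(
                GeneratorConfig(d=5, N=20_000, p=2, seed=500 + s)
            )
            errs.append(estimate_reliabilities(standardize(data.X)).lambda_ - lam)
        assert np.abs(np.mean(errs, axis=0)).max() < 0.01


class TestJacobian:
    def test_matches_finite_differences(self, rng):
        X = IndicatorMatrix(rng.standard_normal((50, 4)))
        lam = rng.uniform(0.3, 0.9, 4)
        J = reliability_jacobian(X, lam)
        xbar = X.values.mean(axis=0)
        h = 1e-6
        for m in range(4):
            lp, lm_ = lam.copy(), lam.copy()
            lp[m] += h
            lm_[m] -= h
            fd = (
                reliability_moment_rows(X.values, xbar, lp).mean(axis=0)
                - reliability_moment_rows(X.values, xbar, lm_).mean(axis=0)
            ) / (2 * h)
            assert np.abs(J[:, m] - fd).max() < 1e-5

    def test_symmetric_under_index_permutation(self):
        # equal covariances + equal lambda: Jacobian invariant to relabeling
        rng_ = np.random.default_rng(0)
        base = rng_.standard_normal(200)
        noise = rng_.standard_normal((200, 3))
        X = IndicatorMatrix(0.7 * base[:, None] + noise)
        lam = np.full(3, 0.7)
        J = reliability_jacobian(X, lam)
        perm = [2, 0, 1]
        Xp = IndicatorMatrix(X.values[:, perm])
        Jp = reliability_jacobian(Xp, lam[perm])
        assert np.allclose(J[np.ix_(perm, perm)], Jp, atol=1e-12)

    def test_invertible_at_solution(self, prepared_p2):
        X, _ = prepared_p2
        est = estimate_reliabilities(X)
        J = reliability_jacobian(X, est.lambda_)
        assert np.linalg.cond(J) < 1e6
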