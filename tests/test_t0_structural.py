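import numpy as np
import pytest

from structest.data_model import (
    GroupingVariable,
    IndicatorMatrix,
    ValidationError,
    group_means,
)
from structest.gmm_engine import empirical_weight
from structest.reliability import (
    estimate_reliabilities,
    reliability_jacobian,
    reliability_moment_rows,
)
from structest.test_t0 import (
    CorrectionError,
    T0Params,
    corrected_weight_t0,
    du_dlambda,
    run_test_t0,
    u_vector_t0,
)

from conftest import make_proportional_dataset


class TestUVector:
    def test_hand_arithmetic(self):
        params = T0Params(gamma=np.zeros(2), beta=np.array([0.6]), ref=0)
        lam = np.array([0.8, 0.4])
        u = u_vector_t0(np.array([0.5, 0.4]), z=2, params=params, lam=lam)
        # layout z-major: entries for z'=1 then z'=2
        assert np.allclose(u[:2], 0.0)
        assert u[2] == pytest.approx(-0.1)
        assert u[3] == pytest.approx(0.1)

    def test_reference_level_exact_fit_is_zero(self):
        gamma = np.array([0.3, -0.2, 0.1])
        params = T0Params(gamma=gamma, beta=np.array([0.5, 0.2]))
        u = u_vector_t0(gamma, z=1, params=params, lam=np.array([0.8, 0.7, 0.6]))
        assert np.allclose(u, 0.0)

    def test_only_own_level_block_nonzero(self, rng):
        params = T0Params(gamma=rng.normal(size=3), beta=rng.normal(size=2))
        lam = rng.uniform(0.3, 0.9, 3)
        u = u_vector_t0(rng.normal(size=3), z=2, params=params, lam=lam)
        assert np.allclose(u[:3], 0) and np.allclose(u[6:], 0)


class TestDuDlambda:
    def test_matches_finite_differences(self, rng):
        d, p = 4, 3
        params = T0Params(
            gamma=rng.normal(size=d), beta=rng.normal(size=p - 1), ref=1
        )
        lam = rng.uniform(0.3, 0.9, d)
        x = rng.normal(size=d)
        for z in range(1, p + 1):
            J = du_dlambda(x, z, params, lam)
            h = 1e-6
            for m in range(d):
                lp, lm_ = lam.copy(), lam.copy()
                lp[m] += h
                lm_[m] -= h
                fd = (
                    u_vector_t0(x, z, params, lp) - u_vector_t0(x, z, params, lm_)
                ) / (2 * h)
                assert np.abs(J[:, m] - fd).max() < 1e-5

    def test_zero_when_beta_zero(self, rng):
        params = T0Params(gamma=rng.normal(size=3), beta=np.zeros(2))
        J = du_dlambda(rng.normal(size=3), 2, params, np.array([0.8, 0.7, 0.6]))
        assert np.allclose(J, 0.0)

    def test_reference_indicator_rows_zero(self, rng):
        d, ref = 4, 2
        params = T0Params(gamma=np.zeros(d), beta=np.array([0.5]), ref=ref)
        lam = rng.uniform(0.3, 0.9, d)
        J = du_dlambda(rng.normal(size=d), 2, params, lam)
        for z in range(2):
            assert np.allclose(J[z * d + ref, :], 0.0)


class TestCorrectedWeight:
    def test_vanishing_adjustment_equals_uncorrected(self, rng):
        U = rng.standard_normal((300, 6))
        V = rng.standard_normal((300, 3))
        B = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        W_adj = corrected_weight_t0(U, V, np.zeros((6, 3)), B)
        W_raw = empirical_weight(U)
        assert np.allclose(W_adj.sigma, W_raw.sigma, atol=1e-12)

    def test_singular_first_stage_raises(self, rng):
        U = rng.standard_normal((50, 4))
        V = rng.standard_normal((50, 2))
        with pytest.raises(CorrectionError):
            corrected_weight_t0(U, V, np.ones((4, 2)), np.zeros((2, 2)))

    def test_reproduces_monte_carlo_covariance(self):
        """Corrected Sigma vs the simulated covariance of sqrt(N)*Ubar with
        plug-in reliabilities, at the true nuisance parameters."""
        from dataclasses import replace

        from scipy import stats

        from structest.synthetic_data import GeneratorConfig, generate_null_dataset
        from structest.test_t0 import _mean_du_dlambda_scale_fixed, _u_rows_t0

        lam_true = np.array([0.8, 0.7, 0.75, 0.65, 0.6])
        cfg = GeneratorConfig(d=5, N=20_000, p=2, seed=100)
        data = generate_null_dataset(cfg)
        # truth for the threshold-at-median mechanism
        c = stats.norm.ppf(0.5)
        e1 = -stats.norm.pdf(c) / stats.norm.cdf(c)
        e2 = stats.norm.pdf(c) / stats.norm.sf(c)
        gamma0 = lam_true * e1
        nu_full0 = np.array([0.0, e2 - e1])

        est = estimate_reliabilities(data.X)
        U0 = _u_rows_t0(data.X, data.Z, gamma0, nu_full0, est.lambda_)
        V = reliability_moment_rows(
            data.X.values, data.X.values.mean(axis=0), est.lambda_
        )
        A = _mean_du_dlambda_scale_fixed(data.Z, nu_full0, 5)
        B = reliability_jacobian(data.X, est.lambda_)
        W = corrected_weight_t0(U0, V, A, B)
        W_raw = empirical_weight(U0)

        S, Nmc = 1500, 4000
        ubars = []
        for s in range(S):
            dd = generate_null_dataset(replace(cfg, N=Nmc, seed=200 + s))
            lam_s = estimate_reliabilities(dd.X).lambda_
            um = _u_rows_t0(dd.X, dd.Z, gamma0, nu_full0, lam_s).mean(axis=0)
            ubars.append(np.sqrt(Nmc) * um)
        Smc = np.cov(np.array(ubars), rowvar=False, bias=True)

        rel = np.linalg.norm(W.sigma - Smc) / np.linalg.norm(Smc)
        rel_raw = np.linalg.norm(W_raw.sigma - Smc) / np.linalg.norm(Smc)
        assert rel < 0.10
        assert rel < rel_raw  # the correction moves Sigma toward the truth


class TestRunT0:
    def test_df_formula(self, prepared_p2, prepared_p4):
        X2, Z2 = prepared_p2
        assert run_test_t0(X2, Z2).df == 4  # d=5, p=2
        X4, Z4 = prepared_p4
        assert run_test_t0(X4, Z4).df == 12  # d=5, p=4

    def test_exactly_proportional_contrasts_give_zero_statistic(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        X, Z = make_proportional_dataset(lam, scale=[0.0, 0.5, -0.3])
        res = run_test_t0(X, Z, lam=lam)
        assert res.statistic < 1e-8
        assert res.p_value == pytest.approx(1.0)

    def test_known_lambda_skips_correction(self, prepared_p2):
        X, Z = prepared_p2
        res = run_test_t0(X, Z, lam=np.array([0.8, 0.7, 0.75, 0.65, 0.6]))
        assert res.diagnostics["corrected"] is False
        assert res.df == 4

    def test_reference_indicator_invariance(self, prepared_p2, rng):
        """The null restriction is symmetric in indicators: permuting the
        columns (which changes which indicator is the reference) must not
        move the statistic."""
        X, Z = prepared_p2
        base = run_test_t0(X, Z)
        perm = rng.permutation(X.d)
        Xp = IndicatorMatrix(X.values[:, perm], standardized=True)
        permuted = run_test_t0(Xp, Z)
        assert abs(base.statistic - permuted.statistic) < 1e-4

    def test_fitted_betas_track_group_contrasts(self, prepared_p2):
        X, Z = prepared_p2
        res = run_test_t0(X, Z)
        ref = res.params["reference_indicator"] - 1
        observed = group_means(X, Z).contrasts()[0, ref]
        assert res.params["beta"][0] == pytest.approx(observed, abs=0.05)

    def test_p1_grouping_rejected(self, prepared_p2):
        X, _ = prepared_p2
        with pytest.raises(ValidationError):
            GroupingVariable(np.ones(X.n, dtype=int), p=1)
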