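import numpy as np
import pytest
import statsmodels.api as sm

from gpflm.exceptions import (
    InputError,
    ShapeError,
    SingularDesignError,
    UndefinedMetricError,
)
from gpflm.model import (
    FitResult,
    build_design,
    fit_quasi_likelihood,
    gcv,
    logit_family,
    predict_mean,
    pseudo_r2,
    reconstruct_coefficient_function,
    score_function,
)


class TestLogitFamily:
    def test_values_at_zero(self, logit):
        assert logit.mean_fn(0.0) == pytest.approx(0.5)
        assert logit.mean_deriv(0.0) == pytest.approx(0.25)
        assert logit.variance_fn(0.5) == pytest.approx(0.25)

    def test_monotone_to_one(self, logit):
        eta = np.array([0.0, 1.0, 10.0, 100.0, 1e4])
        mu = logit.mean_fn(eta)
        assert np.all(np.diff(mu) >= 0)
        assert mu[-1] == pytest.approx(1.0)
        assert np.all(np.isfinite(logit.mean_deriv(eta)))

    def test_information_weight_at_zero(self, logit):
        w = logit.mean_deriv(0.0) ** 2 / logit.variance_fn(logit.mean_fn(0.0))
        assert w == pytest.approx(0.25)

    def test_mean_deriv_matches_numerical_derivative(self, logit):
        eta = np.linspace(-5, 5, 41)
        h = 1e-6
        numeric = (logit.mean_fn(eta + h) - logit.mean_fn(eta - h)) / (2 * h)
        np.testing.assert_allclose(logit.mean_deriv(eta), numeric, atol=1e-6)


class TestBuildDesign:
    def test_column_count(self):
        n = 10
        d = build_design(
            [np.zeros((n, 2)), np.zeros((n, 3))], np.zeros((n, 3)), intercept=True
        )
        assert d.n_columns == 9
        assert d.block_index["X1"] == slice(0, 2)
        assert d.block_index["X2"] == slice(2, 5)
        assert d.block_index["intercept"] == slice(5, 6)
        assert d.block_index["scalar"] == slice(6, 9)

    def test_plain_glm_design(self):
        d = build_design([], np.ones((5, 2)), intercept=True)
        assert d.n_columns == 3
        np.testing.assert_allclose(d.X[:, 0], 1.0)

    def test_block_columns_verbatim(self):
        block = np.eye(4)
        d = build_design([block], None, intercept=True)
        np.testing.assert_allclose(d.X[:, :4], block)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            build_design([np.zeros((4, 2))], np.zeros((5, 1)))


class TestScoreFunction:
    def test_zero_at_saturated_mean(self, logit):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        d = build_design([X], None, intercept=True)
        theta = np.array([0.3, -0.2, 0.1])
        mu = logit.mean_fn(d.X @ theta)
        np.testing.assert_allclose(
            score_function(theta, d, mu, logit), 0.0, atol=1e-12
        )

    def test_balanced_hand_values(self, logit):
        d = build_design([], np.empty((2, 0)), intercept=True)
        u = score_function(np.zeros(1), d, np.array([1.0, 0.0]), logit)
        np.testing.assert_allclose(u, [0.0])
        u = score_function(np.zeros(1), d, np.array([1.0, 1.0]), logit)
        np.testing.assert_allclose(u, [1.0])


class TestFitQuasiLikelihood:
    def test_intercept_only_closed_form(self, logit):
        Y = np.array([1.0, 0.0, 0.0, 0.0] * 25)
        d = build_design([], np.empty((100, 0)), intercept=True)
        fit = fit_quasi_likelihood(d, Y, logit)
        assert fit.converged
        assert fit.alpha_hat == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)

    def test_separation_reported_not_hidden(self, logit):
        d = build_design([], np.empty((10, 0)), intercept=True)
        fit = fit_quasi_likelihood(d, np.ones(10), logit)
        assert not fit.converged

    def test_grid_search_oracle(self, logit):
        # brute-force maximization of the Bernoulli log-likelihood over a
        # fine one-parameter grid, independent of the IWLS path
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        grid = np.linspace(-3, 3, 600001)
        eta = np.outer(grid, x)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum(axis=1)
        oracle = grid[np.argmax(ll)]
        d = build_design([x[:, None]], None, intercept=False)
        fit = fit_quasi_likelihood(d, y, logit)
        assert fit.converged
        assert fit.theta_hat[0] == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_statsmodels_logit(self, seed, logit):
        rng = np.random.default_rng(seed)
        n, q = 50, 3
        X = rng.normal(size=(n, q))
        eta = X @ rng.uniform(-1, 1, q)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        d = build_design([X], None, intercept=True)
        fit = fit_quasi_likelihood(d, y, logit)
        ref = sm.Logit(y, np.column_stack([X, np.ones(n)])).fit(disp=0)
        assert fit.converged
        np.testing.assert_allclose(fit.theta_hat, ref.params, atol=1e-6)

    def test_permutation_invariance(self, logit):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 2))
        y = rng.binomial(1, 0.5, 60).astype(float)
        d = build_design([X], None, intercept=True)
        fit = fit_quasi_likelihood(d, y, logit)
        perm = rng.permutation(60)
        d2 = build_design([X[perm]], None, intercept=True)
        fit2 = fit_quasi_likelihood(d2, y[perm], logit)
        np.testing.assert_allclose(fit.theta_hat, fit2.theta_hat, atol=1e-9)

    def test_column_scaling_equivariance(self, logit):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 2))
        eta = X @ [0.5, -0.5]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        d = build_design([X], None, intercept=True)
        fit = fit_quasi_likelihood(d, y, logit)
        c = 4.0
        Xs = X.copy()
        Xs[:, 0] *= c
        fit2 = fit_quasi_likelihood(build_design([Xs], None, intercept=True), y, logit)
        assert fit2.theta_hat[0] == pytest.approx(fit.theta_hat[0] / c, rel=1e-6)

    def test_singular_design_advises_ridge(self, logit):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = np.column_stack([x, x])  # exactly collinear
        y = rng.binomial(1, 0.5, 30).astype(float)
        d = build_design([X], None, intercept=True)
        with pytest.raises(SingularDesignError, match="ridge"):
            fit_quasi_likelihood(d, y, logit)
        fit = fit_quasi_likelihood(d, y, logit, ridge=1e-6)
        assert np.all(np.isfinite(fit.theta_hat))

    def test_nonfinite_response_rejected(self, logit):
        d = build_design([], np.empty((5, 0)), intercept=True)
        with pytest.raises(InputError):
            fit_quasi_likelihood(d, np.array([1, 0, np.nan, 0, 1]), logit)

    def test_underdetermined_rejected_without_ridge(self, logit):
        d = build_design([np.eye(3)], None, intercept=True)
        with pytest.raises(InputError):
            fit_quasi_likelihood(d, np.array([1.0, 0, 1]), logit)

    def test_parameter_recovery_large_n(self, logit):
        from gpflm.simulation import SimConfig, run_replicate, simulate_dataset
        from gpflm.inference import nu_and_gamma_se

        cfg = SimConfig(n=5000, seed=3, coef_scale=0.1, center_z3=True)
        ds = simulate_dataset(cfg, seed=3)
        rec = run_replicate(ds, fixed_p=(3, 5), return_details=True)
        fit = rec["details"]["fit"]
        nu_hat, se = nu_and_gamma_se(ds.Z, fit.eta_hat, fit.mu_hat, logit, 5000)
        gamma_true = ds.truth["gamma"]
        assert np.all(np.abs(fit.gamma_hat - gamma_true) < 3 * se)


class TestReconstructCoefficientFunction:
    def test_unit_vector_returns_first_eigenfunction(self, cosine_basis):
        _, phi = cosine_basis
        np.testing.assert_allclose(
            reconstruct_coefficient_function(np.array([1.0]), phi), phi[0]
        )

    def test_zero_coefficients(self, cosine_basis):
        _, phi = cosine_basis
        np.testing.assert_allclose(
            reconstruct_coefficient_function(np.zeros(2), phi), 0.0
        )

    def test_hand_summed_curve(self):
        phi = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, -1.0]])
        out = reconstruct_coefficient_function(np.array([2.0, -1.0]), phi)
        np.testing.assert_allclose(out, [2.0, -1.0, 3.0])

    def test_length_mismatch_rejected(self, cosine_basis):
        _, phi = cosine_basis
        with pytest.raises(ShapeError):
            reconstruct_coefficient_function(np.zeros(5), phi)


class TestPredictMean:
    def test_zero_theta_gives_half(self, logit):
        d = build_design([], np.empty((4, 0)), intercept=True)
        np.testing.assert_allclose(predict_mean(np.zeros(1), d, logit), 0.5)

    def test_no_overflow_for_large_eta(self, logit):
        d = build_design([np.full((3, 1), 1e4)], None, intercept=False)
        mu = predict_mean(np.array([10.0]), d, logit)
        np.testing.assert_allclose(mu, 1.0)

    def test_round_trip_with_intercept_fit(self, logit):
        Y = np.array([1.0, 0.0, 0.0, 0.0] * 25)
        d = build_design([], np.empty((100, 0)), intercept=True)
        fit = fit_quasi_likelihood(d, Y, logit)
        np.testing.assert_allclose(predict_mean(fit, d), 0.25, atol=1e-6)


class TestPseudoR2:
    def _mkfit(self, ll):
        return FitResult(
            theta_hat=np.zeros(1), b_blocks={}, alpha_hat=0.0,
            gamma_hat=np.empty(0), eta_hat=np.zeros(1), mu_hat=np.full(1, 0.5),
            loglik=ll, n_iter=1, converged=True, score_norm=0.0,
        )

    def test_equal_likelihoods(self):
        assert pseudo_r2(self._mkfit(-5.0), self._mkfit(-5.0), 10) == (0.0, 0.0)

    def test_formula_arithmetic(self):
        mcf, r2ml = pseudo_r2(self._mkfit(-10.0), self._mkfit(-100.0), 100)
        assert mcf == pytest.approx(0.9)
        assert r2ml == pytest.approx(1 - np.exp(-1.8))

    def test_perfect_fit_limit(self):
        mcf, _ = pseudo_r2(self._mkfit(-1e-12), self._mkfit(-100.0), 100)
        assert mcf == pytest.approx(1.0)

    def test_zero_null_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pseudo_r2(self._mkfit(-1.0), self._mkfit(0.0), 10)


class TestGCV:
    def test_intercept_only_hand_value(self, logit):
        Y = np.array([1.0, 0.0, 1.0, 0.0])
        d = build_design([], np.empty((4, 0)), intercept=True)
        fit = fit_quasi_likelihood(d, Y, logit)
        assert gcv(fit, d, Y) == pytest.approx(0.25 / 0.75**2, rel=1e-6)

    def test_perfect_fit_is_zero(self, logit):
        # near-deterministic fit: mu ~ Y so RSS ~ 0
        x = np.array([-1.0, -1, -1, 1, 1, 1, -1, 1])
        Y = (x > 0).astype(float)
        d = build_design([x[:, None]], None, intercept=False)
        fit = fit_quasi_likelihood(d, Y, logit, ridge=1e-10, max_iter=200)
        assert gcv(fit, d, Y) < 1e-6

    def test_saturated_design_rejected(self, logit):
        X = np.eye(2)
        d = build_design([X], None, intercept=False)
        fit = FitResult(
            theta_hat=np.zeros(2), b_blocks={"X1": np.zeros(2)}, alpha_hat=0.0,
            gamma_hat=np.empty(0), eta_hat=np.zeros(2), mu_hat=np.full(2, 0.5),
            loglik=-1.0, n_iter=1, converged=True, score_norm=0.0,
            family_name="logit",
        )
        with pytest.raises(UndefinedMetricError):
            gcv(fit, d, np.array([1.0, 0.0]))
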