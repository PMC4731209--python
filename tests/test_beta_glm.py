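"""Beta regression: likelihood, sampler, deviance machinery, model selection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from ignoscore.beta_glm import (
    CHI2_CRITICAL_1DF,
    BoundaryResponseError,
    MCMCSettings,
    ModelSpec,
    PosteriorFit,
    Standardization,
    beta_loglik,
    boundary_adjust,
    build_design,
    compare_nested,
    deviance,
    fitted_curve,
    r_squared,
    sample_posterior,
    select_model,
)
from ignoscore.synthetic import simulate_beta_response


def brute_force_loglik(y, mu, phi):
    """Independent scalar-loop Beta log-density via math.lgamma."""
    total = 0.0
    for yi, mi in zip(np.atleast_1d(y), np.broadcast_to(mu, np.shape(y))):
        a, b = mi * phi, (1 - mi) * phi
        total += (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
                  + (a - 1) * math.log(yi) + (b - 1) * math.log(1 - yi))
    return total


def make_fit(degree=0, dev=0.0, covariate="cov", alpha=0.0, beta=(), phi=2.0,
             n_draws=10, std=None, x_range=None, X=None, y=None) -> PosteriorFit:
    """Degenerate fit whose posterior is a point mass — handy for exact edges."""
    names = ["alpha"] + [f"beta{k+1}" for k in range(degree)] + ["phi"]
    vals = [alpha, *beta, phi]
    samples = {p: np.full((1, n_draws), v) for p, v in zip(names, vals)}
    return PosteriorFit(
        model=ModelSpec(covariate_name=covariate, degree=degree),
        samples=samples, deviance=dev, n_iterations=n_draws,
        rhat={p: 1.0 for p in names}, seed=0,
        standardization=std or Standardization(enabled=False),
        x_range=x_range, X=X, y=y,
    )


class TestBetaLoglik:
    def test_uniform_density_has_zero_loglik(self, rng):
        """mu=0.5, phi=2 is Beta(1,1): density 1 everywhere on (0,1)."""
        y = rng.uniform(0.01, 0.99, 50)
        assert beta_loglik(y, np.full(50, 0.5), 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_beta22_closed_form_at_half(self):
        # Beta(2,2) density at 0.5 is 1.5
        assert beta_loglik(np.array([0.5]), np.array([0.5]), 4.0) == pytest.approx(np.log(1.5), abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(0.05, 0.95), st.floats(0.5, 50))
    def test_symmetry(self, y, mu, phi):
        lhs = beta_loglik(np.array([y]), np.array([mu]), phi)
        rhs = beta_loglik(np.array([1 - y]), np.array([1 - mu]), phi)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    def test_boundary_response_is_domain_error(self):
        with pytest.raises(BoundaryResponseError):
            beta_loglik(np.array([0.0, 0.5]), np.array([0.5, 0.5]), 2.0)
        with pytest.raises(BoundaryResponseError):
            beta_loglik(np.array([1.0]), np.array([0.5]), 2.0)

    def test_matches_brute_force_lgamma(self, rng):
        y = rng.uniform(0.01, 0.99, 40)
        mu = rng.uniform(0.05, 0.95, 40)
        phi = 7.3
        assert beta_loglik(y, mu, phi) == pytest.approx(brute_force_loglik(y, mu, phi), rel=1e-12)


class TestBoundaryAdjust:
    def test_half_is_fixed_point(self):
        assert boundary_adjust(np.array([0.5]), n=100)[0] == 0.5

    def test_formula_values(self):
        assert boundary_adjust(np.array([1.0]), n=100)[0] == pytest.approx(0.995)
        assert boundary_adjust(np.array([0.0]), n=10)[0] == pytest.approx(0.05)

    def test_order_preserving_and_interior(self, rng):
        y = np.sort(rng.uniform(0, 1, 100))
        y[0], y[-1] = 0.0, 1.0
        out = boundary_adjust(y)
        assert ((out > 0) & (out < 1)).all()
        assert (np.diff(out) >= 0).all()

    def test_too_few_cells_is_domain_error(self):
        with pytest.raises(ValueError):
            boundary_adjust(np.array([0.5]), n=1)


class TestBuildDesign:
    def test_degree_zero_is_empty_matrix(self):
        X, std = build_design([1.0, 2.0, 3.0], 0)
        assert X.shape == (3, 0)
        assert not std.enabled

    def test_degree_one_unstandardized_passthrough(self):
        X, _ = build_design([1.0, 2.0, 3.0], 1, standardize=False)
        np.testing.assert_array_equal(X[:, 0], [1.0, 2.0, 3.0])

    def test_quadratic_column_is_square_of_standardized_first(self):
        X, std = build_design([1.0, 2.0, 3.0], 2, standardize=True)
        np.testing.assert_allclose(X[:, 1], X[:, 0] ** 2, atol=1e-12)
        assert X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        # round trip through the standardization record
        np.testing.assert_allclose(std.inverse(X[:, 0]), [1.0, 2.0, 3.0], atol=1e-12)

    def test_zero_variance_with_standardize_is_domain_error(self):
        with pytest.raises(ValueError):
            build_design([2.0, 2.0, 2.0], 1, standardize=True)


class TestSampler:
    def test_parameter_recovery_within_three_sd(self):
        rng = np.random.default_rng(5)
        X, std = build_design(rng.normal(0, 1, 2000), 1)
        y = simulate_beta_response(X, -1.0, 0.5, 20.0, seed=6)
        fit = sample_posterior(ModelSpec(degree=1), X, y,
                               MCMCSettings(iterations=1500, burn_in=1200, chains=2, seed=1),
                               standardization=std)
        truth = {"alpha": -1.0, "beta1": 0.5, "phi": 20.0}
        for p, t in truth.items():
            assert abs(fit.means[p] - t) < 3 * fit.sds[p]

    def test_null_model_mean_matches_sample_mean(self, fast_mcmc, rng):
        y = rng.beta(2.0, 3.0, 600)
        X, _ = build_design(y * 0, 0, standardize=False)
        fit = sample_posterior(ModelSpec(degree=0), X, y, fast_mcmc)
        post_mean_mu = expit(fit.flat("alpha")).mean()
        mc_se = y.std(ddof=1) / np.sqrt(y.size)
        assert abs(post_mean_mu - y.mean()) < 2 * mc_se + 2 * expit(fit.flat("alpha")).std()

    def test_seed_determinism_bit_identical(self, fast_mcmc, rng):
        X, _ = build_design(rng.normal(0, 1, 300), 1)
        y = simulate_beta_response(X, 0.0, 0.3, 10.0, seed=2)
        f1 = sample_posterior(ModelSpec(degree=1), X, y, fast_mcmc)
        f2 = sample_posterior(ModelSpec(degree=1), X, y, fast_mcmc)
        for p in f1.param_names:
            np.testing.assert_array_equal(f1.samples[p], f2.samples[p])
        assert f1.deviance == f2.deviance

    def test_different_seed_different_draws(self, fast_mcmc, rng):
        X, _ = build_design(rng.normal(0, 1, 300), 1)
        y = simulate_beta_response(X, 0.0, 0.3, 10.0, seed=2)
        f1 = sample_posterior(ModelSpec(degree=1), X, y, fast_mcmc)
        f2 = sample_posterior(ModelSpec(degree=1), X, y,
                              MCMCSettings(iterations=800, burn_in=800, chains=2, seed=99))
        assert not np.array_equal(f1.samples["alpha"], f2.samples["alpha"])

    def test_boundary_responses_rejected(self, fast_mcmc):
        X, _ = build_design(np.linspace(0, 1, 10), 1)
        y = np.linspace(0, 1, 10)
        with pytest.raises(BoundaryResponseError):
            sample_posterior(ModelSpec(degree=1), X, y, fast_mcmc)

    def test_posterior_mode_matches_independent_mle(self):
        """With near-flat priors the posterior mode coincides with the MLE
        found by an independent optimizer on the brute-force likelihood."""
        rng = np.random.default_rng(8)
        X, _ = build_design(rng.normal(0, 1, 200), 1)
        y = simulate_beta_response(X, -0.8, 0.9, 30.0, seed=9)
        fit = sample_posterior(ModelSpec(degree=1), X, y,
                               MCMCSettings(iterations=1500, burn_in=1200, chains=2, seed=3))
        mode = fit.posterior_mode()

        def neg_ll(t):
            return -beta_loglik(y, expit(t[0] + X[:, 0] * t[1]), np.exp(t[2]))

        res = minimize(neg_ll, np.array([0.0, 0.0, np.log(10)]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        mle = {"alpha": res.x[0], "beta1": res.x[1], "phi": np.exp(res.x[2])}
        for p in ("alpha", "beta1", "phi"):
            tol = max(0.05, 0.05 * abs(mle[p]))
            assert abs(mode[p] - mle[p]) < tol, f"{p}: mode {mode[p]} vs MLE {mle[p]}"


class TestDeviance:
    def test_uniform_edge_case_zero_deviance(self, rng):
        """Posterior means implying Beta(1,1) everywhere give D = 0."""
        y = rng.uniform(0.01, 0.99, 80)
        fit = make_fit(degree=0, alpha=0.0, phi=2.0, X=np.empty((80, 0)), y=y)
        assert deviance(fit) == pytest.approx(0.0, abs=1e-10)

    def test_plugin_deviance_equals_minus_twice_brute_force(self, rng):
        y = rng.uniform(0.05, 0.95, 60)
        x = rng.normal(0, 1, 60)
        X = x[:, None]
        fit = make_fit(degree=1, alpha=0.3, beta=(0.4,), phi=8.0, X=X, y=y)
        d = deviance(fit)
        expected = -2.0 * brute_force_loglik(y, expit(0.3 + 0.4 * x), 8.0)
        assert d == pytest.approx(expected, rel=1e-8)

    def test_deviance_drops_from_null_to_linear_under_true_slope(self, fast_mcmc, rng):
        x = rng.normal(0, 1, 800)
        X1, _ = build_design(x, 1)
        X0, _ = build_design(x, 0)
        y = simulate_beta_response(X1, 0.0, 0.8, 15.0, seed=4)
        f0 = sample_posterior(ModelSpec(degree=0), X0, y, fast_mcmc)
        f1 = sample_posterior(ModelSpec(degree=1), X1, y, fast_mcmc)
        assert f1.deviance < f0.deviance


class TestComparisonAndSelection:
    def test_exact_threshold_improves(self):
        f0 = make_fit(degree=0, dev=100.0)
        f1 = make_fit(degree=1, dev=100.0 - 3.84, beta=(0.1,))
        assert compare_nested(f0, f1).improves is True

    def test_just_below_threshold_does_not_improve(self):
        f0 = make_fit(degree=0, dev=100.0)
        f1 = make_fit(degree=1, dev=100.0 - 3.83, beta=(0.1,))
        assert compare_nested(f0, f1).improves is False

    def test_threshold_matches_chi_square_95th_percentile(self):
        from scipy.stats import chi2
        assert CHI2_CRITICAL_1DF == pytest.approx(chi2.ppf(0.95, df=1), abs=0.005)

    def test_non_nested_is_usage_error(self):
        f1 = make_fit(degree=1, dev=10.0, beta=(0.1,))
        f1b = make_fit(degree=1, dev=9.0, beta=(0.2,))
        with pytest.raises(ValueError):
            compare_nested(f1, f1b)

    def test_antisymmetry_of_delta(self):
        f0 = make_fit(degree=0, dev=50.0)
        f1 = make_fit(degree=1, dev=40.0, beta=(0.1,))
        assert compare_nested(f0, f1).delta_deviance == pytest.approx(10.0)

    def test_quadratic_never_chosen_when_linear_rejected(self, rng):
        y = rng.uniform(0.2, 0.8, 50)
        X = np.empty((50, 0))
        f0 = make_fit(degree=0, dev=100.0, X=X, y=y, phi=5.0, alpha=0.0)
        f1 = make_fit(degree=1, dev=99.0, beta=(0.0,), X=rng.normal(0, 1, (50, 1)), y=y, phi=5.0)
        # quadratic would beat the null outright, but the path goes through linear
        f2 = make_fit(degree=2, dev=10.0, beta=(0.0, 0.0), X=rng.normal(0, 1, (50, 2)), y=y, phi=5.0)
        sel = select_model(f0, f1, f2)
        assert sel.chosen_degree == 0
        assert len(sel.comparisons) == 1

    def test_stepwise_accepts_linear_then_quadratic(self, rng):
        y = rng.uniform(0.2, 0.8, 50)
        f0 = make_fit(degree=0, dev=100.0, X=np.empty((50, 0)), y=y, phi=5.0)
        f1 = make_fit(degree=1, dev=80.0, beta=(0.1,), X=rng.normal(0, 1, (50, 1)), y=y, phi=5.0)
        f2 = make_fit(degree=2, dev=70.0, beta=(0.1, 0.1), X=rng.normal(0, 1, (50, 2)), y=y, phi=5.0)
        sel = select_model(f0, f1, f2)
        assert sel.chosen_degree == 2
        assert [c.improves for c in sel.comparisons] == [True, True]


class TestRSquared:
    def test_null_against_itself_is_zero(self, rng):
        y = rng.beta(2, 2, 100)
        f0 = make_fit(degree=0, dev=5.0, alpha=0.0, phi=4.0, X=np.empty((100, 0)), y=y)
        assert r_squared(f0, f0) == 0.0

    def test_null_simulation_concentrates_near_zero(self, fast_mcmc):
        """Data with no covariate effect should explain ~nothing."""
        r2s = []
        for rep in range(6):
            rng = np.random.default_rng(50 + rep)
            x = rng.normal(0, 1, 400)
            X1, _ = build_design(x, 1)
            X0, _ = build_design(x, 0)
            y = simulate_beta_response(X1, -0.4, 0.0, 8.0, seed=60 + rep)
            m = MCMCSettings(iterations=600, burn_in=600, chains=2, seed=70 + rep)
            f0 = sample_posterior(ModelSpec(degree=0), X0, y, m)
            f1 = sample_posterior(ModelSpec(degree=1), X1, y, m)
            r2s.append(r_squared(f1, f0))
        assert np.median(r2s) < 5.0

    def test_r_squared_grows_with_precision_under_strong_signal(self):
        """Holding the signal fixed, higher phi leaves less unexplained noise."""
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 800)
        X1, std = build_design(x, 1)
        X0, _ = build_design(x, 0)
        r2s = []
        for phi in (5.0, 50.0, 500.0):
            y = simulate_beta_response(X1, 0.0, 1.5, phi, seed=int(phi))
            m = MCMCSettings(iterations=1200, burn_in=1200, chains=2, seed=12)
            f0 = sample_posterior(ModelSpec(degree=0), X0, y, m)
            f1 = sample_posterior(ModelSpec(degree=1), X1, y, m, standardization=std)
            r2s.append(r_squared(f1, f0))
        assert r2s == sorted(r2s)
        assert r2s[-1] > 95.0


class TestFittedCurve:
    def test_flat_logit_gives_half(self):
        fit = make_fit(degree=1, alpha=0.0, beta=(0.0,), x_range=(-1, 1))
        _, mu = fitted_curve(fit, np.linspace(-1, 1, 7))
        np.testing.assert_allclose(mu, 0.5, atol=1e-12)

    def test_large_negative_intercept_drives_mu_to_zero(self):
        fit = make_fit(degree=0, alpha=-20.0)
        _, mu = fitted_curve(fit, np.array([0.0]))
        assert mu[0] < 1e-8

    def test_curve_at_covariate_mean_is_inverse_logit_alpha(self):
        std = Standardization(mean=7.0, sd=2.0, enabled=True)
        fit = make_fit(degree=2, alpha=0.7, beta=(0.3, -0.2), std=std, x_range=(0, 14))
        _, mu = fitted_curve(fit, np.array([7.0]))  # x* = 0 here
        assert mu[0] == pytest.approx(expit(0.7), abs=1e-12)
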