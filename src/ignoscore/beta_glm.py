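"""Bayesian Beta regression of ignorance scores on single geographic covariates.

The response I_i in (0, 1) is modelled as

    I_i ~ Beta(a_i, b_i),   a_i = mu_i * phi,   b_i = (1 - mu_i) * phi,
    logit(mu_i) = alpha + X_i beta,

with vague priors phi ~ Gamma(0.1, 0.1) and alpha, beta ~ Normal(0, 1000)
(variance parameterisation, SD ~ 31.6).  Each covariate is modelled on its
own, at three nested degrees: null (intercept only), linear, quadratic.

Model fit is compared through the plug-in deviance D = -2 log L evaluated at
the posterior means; between nested models the deviance difference is judged
against the chi-square(1) 95th percentile, 3.84, per added parameter, and the
explained variation is the deviance-R² = 100 (D_null - D) / D_null.

The sampler is an adaptive random-walk Metropolis: independent seeded chains
whose proposal covariance is tuned during burn-in (scaled empirical
covariance of the chain history) and frozen afterwards, with phi sampled on
the log scale (Jacobian included) to preserve positivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

logger = logging.getLogger(__name__)

#: chi-square(1 df) 95th percentile at the conventional printed precision;
#: the minimum deviance drop required per parameter added to a nested model.
CHI2_CRITICAL_1DF = 3.84

_RHAT_LIMIT = 1.1


class BoundaryResponseError(ValueError):
    """Raised when responses touch {0, 1}; apply boundary_adjust first."""


@dataclass(frozen=True)
class Standardization:
    """Centre/scale record so fitted curves can be reported in original units."""

    mean: float = 0.0
    sd: float = 1.0
    enabled: bool = True

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.mean) / self.sd if self.enabled else x

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return z * self.sd + self.mean if self.enabled else z


@dataclass(frozen=True)
class ModelSpec:
    """One single-covariate Beta regression: degree 0 (null), 1 or 2."""

    covariate_name: str = ""
    degree: int = 1
    standardize: bool = True
    prior_phi_shape: float = 0.1
    prior_phi_rate: float = 0.1
    prior_coef_sd: float = sqrt(1000.0)

    def __post_init__(self) -> None:
        if self.degree not in (0, 1, 2):
            raise ValueError(f"degree must be 0, 1 or 2, got {self.degree}")
        if min(self.prior_phi_shape, self.prior_phi_rate, self.prior_coef_sd) <= 0:
            raise ValueError("prior hyperparameters must be positive")

    @property
    def n_params(self) -> int:
        """alpha + degree slope terms + phi."""
        return 2 + self.degree


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 5000   # retained draws per chain after burn-in
    burn_in: int = 2000
    chains: int = 3
    seed: int = 0
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.burn_in < 0 or self.chains < 1:
            raise ValueError("invalid MCMC settings")


@dataclass
class PosteriorFit:
    """Posterior samples and summaries for one fitted Beta regression."""

    model: ModelSpec
    samples: dict[str, np.ndarray]          # name -> (chains, iterations)
    deviance: float
    n_iterations: int
    rhat: dict[str, float]
    seed: int
    standardization: Standardization
    x_range: tuple[float, float] | None = None   # observed covariate range, original units
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    taxon: str = ""
    o_half: float | None = None

    @property
    def param_names(self) -> list[str]:
        return ["alpha"] + [f"beta{k + 1}" for k in range(self.model.degree)] + ["phi"]

    def flat(self, name: str) -> np.ndarray:
        return self.samples[name].reshape(-1)

    @property
    def means(self) -> dict[str, float]:
        return {p: float(self.flat(p).mean()) for p in self.param_names}

    @property
    def sds(self) -> dict[str, float]:
        return {p: float(self.flat(p).std(ddof=1)) for p in self.param_names}

    @property
    def converged(self) -> bool:
        return all(r <= _RHAT_LIMIT for r in self.rhat.values())

    def coefficients(self) -> tuple[float, float, float]:
        """Posterior-mean (alpha, beta1, beta2) with absent terms as 0."""
        m = self.means
        return m["alpha"], m.get("beta1", 0.0), m.get("beta2", 0.0)

    def summary(self):
        """Tidy per-parameter summary table (mean, sd, 95% interval, R̂)."""
        import pandas as pd

        rows = []
        for p in self.param_names:
            draws = self.flat(p)
            rows.append({
                "parameter": p,
                "mean": draws.mean(),
                "sd": draws.std(ddof=1),
                "q2.5": np.percentile(draws, 2.5),
                "q97.5": np.percentile(draws, 97.5),
                "rhat": self.rhat[p],
            })
        return pd.DataFrame(rows)

    def posterior_mode(self) -> dict[str, float]:
        """Joint posterior mode, found by polishing the best posterior draw.

        With the default vague priors this is numerically close to the
        maximum-likelihood estimate.
        """
        if self.X is None or self.y is None:
            raise ValueError("fit does not retain its design/response")
        logpost = _make_log_posterior(self.model, self.X, self.y)
        names = self.param_names
        theta_draws = np.column_stack([self.flat(p) for p in names])
        theta_draws[:, -1] = np.log(theta_draws[:, -1])  # phi -> log phi
        lp = np.array([logpost(t) for t in theta_draws])
        start = theta_draws[int(np.argmax(lp))]
        res = minimize(lambda t: -logpost(t), start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        mode = res.x
        out = dict(zip(names, mode))
        out["phi"] = float(np.exp(mode[-1]))
        return out


@dataclass
class ModelComparison:
    """Nested Δ-deviance comparison with the 3.84-per-parameter rule."""

    reduced: ModelSpec
    full: ModelSpec
    delta_deviance: float
    params_added: int
    improves: bool
    r_squared_full: float | None = None


@dataclass
class ModelSelection:
    chosen: PosteriorFit
    comparisons: list[ModelComparison]

    @property
    def chosen_degree(self) -> int:
        return self.chosen.model.degree


def build_design(
    values: Sequence[float] | np.ndarray,
    degree: int,
    standardize: bool = True,
) -> tuple[np.ndarray, Standardization]:
    """Design matrix for a single covariate at the given polynomial degree.

    Degree 0 gives an empty (n, 0) matrix (intercept-only model); degree 1 a
    single column x*; degree 2 the pair (x*, x*²), where x* is the covariate
    optionally centred and scaled.  The standardisation record is returned so
    curves and thresholds can be mapped back to original units.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate values must be finite")
    if degree not in (0, 1, 2):
        raise ValueError(f"degree must be 0, 1 or 2, got {degree}")
    if standardize and degree > 0:
        sd = float(x.std(ddof=0))
        if sd == 0:
            raise ValueError("cannot standardize a zero-variance covariate")
        std = Standardization(mean=float(x.mean()), sd=sd, enabled=True)
    else:
        std = Standardization(enabled=False)
    z = std.transform(x)
    cols = [z ** (k + 1) for k in range(degree)]
    X = np.column_stack(cols) if cols else np.empty((x.size, 0))
    return X, std


def beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Total Beta log-likelihood under the mean/precision parameterisation.

    Sum over cells of log Beta(y_i; a_i, b_i) with a_i = mu_i*phi and
    b_i = (1-mu_i)*phi.  Responses and means must lie strictly inside (0, 1).
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if ((y <= 0) | (y >= 1)).any():
        raise BoundaryResponseError(
            "responses on the boundary {0,1}; apply boundary_adjust before fitting")
    if ((mu <= 0) | (mu >= 1)).any():
        raise ValueError("means must lie strictly inside (0, 1)")
    if not phi > 0:
        raise ValueError(f"phi must be positive, got {phi}")
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (gammaln(phi) - gammaln(a) - gammaln(b)
          + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return float(ll.sum())


def beta_saturated_loglik(y: np.ndarray, phi: float) -> float:
    """Log-likelihood of the saturated Beta model at precision phi.

    Reference point for GLM-style deviance: each cell's mean is set to its
    per-cell maximiser, the root of psi(mu phi) - psi((1-mu) phi) =
    log(y/(1-y)) (solved by a few Newton steps from mu = y).  Using the
    exact maximiser rather than the common mu_i = y_i convention keeps the
    deviance non-negative at small phi, where the two differ noticeably.
    """
    from scipy.special import polygamma, psi

    y = np.asarray(y, dtype=float)
    if not phi > 0:
        raise ValueError(f"phi must be positive, got {phi}")
    target = np.log(y) - np.log1p(-y)
    mu = y.copy()
    for _ in range(30):
        g = psi(mu * phi) - psi((1.0 - mu) * phi) - target
        gp = phi * (polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi))
        step = g / gp
        mu_new = np.clip(mu - step, 1e-12, 1.0 - 1e-12)
        if np.max(np.abs(mu_new - mu)) < 1e-13:
            mu = mu_new
            break
        mu = mu_new
    return beta_loglik(y, mu, phi)


def boundary_adjust(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Squeeze responses from [0, 1] into (0, 1) (Smithson–Verkuilen).

    y' = (y (n-1) + 1/2) / n with n the number of cells; order-preserving,
    with 0.5 as fixed point.  Needed because unsampled cells have ignorance
    exactly 1, which the Beta likelihood excludes.
    """
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError(f"boundary_adjust needs n >= 2, got {n}")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


def _make_log_posterior(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray
) -> Callable[[np.ndarray], float]:
    """Unnormalised log posterior over theta = (alpha, beta..., log phi)."""
    y = np.asarray(y, dtype=float)
    log_y = np.log(y)
    log_1my = np.log1p(-y)
    coef_var = spec.prior_coef_sd ** 2
    k, r = spec.prior_phi_shape, spec.prior_phi_rate

    def logpost(theta: np.ndarray) -> float:
        coefs, t = theta[:-1], theta[-1]
        if abs(t) > 50:  # phi under/overflow guard
            return -np.inf
        phi = np.exp(t)
        eta = coefs[0] + (X @ coefs[1:] if X.shape[1] else 0.0)
        mu = expit(eta)
        if (mu <= 0).any() or (mu >= 1).any():
            return -np.inf
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (gammaln(phi) - gammaln(a) - gammaln(b)
              + (a - 1.0) * log_y + (b - 1.0) * log_1my).sum()
        if not np.isfinite(ll):
            return -np.inf
        lp = -0.5 * (coefs @ coefs) / coef_var      # alpha, beta ~ N(0, var)
        lp += k * t - r * phi                       # Gamma(k, r) on phi + log-scale Jacobian
        return float(ll + lp)

    return logpost


def _initial_theta(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Data-driven start (logit-scale least squares + moment phi), jittered per chain."""
    theta = np.zeros(spec.n_params)
    z = logit(np.clip(y, 1e-6, 1 - 1e-6))
    if X.shape[1]:
        A = np.column_stack([np.ones_like(z), X])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        theta[:-1] = np.clip(coef, -10, 10)
        resid_var = float(max(np.var(z - A @ theta[:-1]), 1e-6))
        # logistic-scale residual variance ~ trigamma-based; crude moment proxy
        m = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        phi0 = np.clip(1.0 / (resid_var * m * (1 - m)), 0.5, 1e5)
    else:
        m = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        v = float(max(y.var(), 1e-6))
        phi0 = np.clip(m * (1 - m) / v - 1.0, 0.5, 1e5)
        theta[0] = logit(m)
    theta[-1] = np.log(phi0)
    theta[:-1] += rng.normal(0.0, 0.25, size=spec.n_params - 1)
    theta[-1] += rng.normal(0.0, 0.4)
    return theta


def _run_chain(
    logpost: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    settings: MCMCSettings,
    rng: np.random.Generator,
) -> np.ndarray:
    """One adaptive-Metropolis chain; returns retained draws (iterations, dim)."""
    dim = theta0.size
    theta = theta0.copy()
    lp = logpost(theta)
    for _ in range(50):  # bounded re-initialisation from jittered start
        if np.isfinite(lp):
            break
        theta = theta0 + rng.normal(0.0, 0.5, size=dim)
        lp = logpost(theta)
    else:
        raise RuntimeError("could not find a finite-posterior starting point")

    scale = 2.38 ** 2 / dim
    chol = np.linalg.cholesky(np.eye(dim) * 0.05)
    history = np.empty((settings.burn_in, dim))
    for it in range(settings.burn_in):
        prop = theta + chol @ rng.standard_normal(dim)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
        history[it] = theta
        if it >= 100 and (it + 1) % settings.adapt_interval == 0:
            cov = np.cov(history[: it + 1].T).reshape(dim, dim)
            chol = np.linalg.cholesky(scale * cov + 1e-9 * np.eye(dim))

    draws = np.empty((settings.iterations, dim))
    for it in range(settings.iterations):
        prop = theta + chol @ rng.standard_normal(dim)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
        draws[it] = theta
    return draws


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    Each chain is halved, giving 2m sequences of length n/2; R̂ compares the
    between- and within-sequence variances.
    """
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    seqs = chains[:, : 2 * half].reshape(m * 2, half)
    w = seqs.var(axis=1, ddof=1).mean()
    b = half * seqs.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def sample_posterior(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    mcmc: MCMCSettings,
    standardization: Standardization | None = None,
    x_range: tuple[float, float] | None = None,
    taxon: str = "",
    o_half: float | None = None,
) -> PosteriorFit:
    """Draw from the joint posterior of (alpha, beta, phi).

    Runs ``mcmc.chains`` independent adaptive-Metropolis chains and retains
    ``mcmc.iterations`` post-burn-in draws per chain.  Identical settings and
    seed reproduce the samples bit-for-bit.  Convergence is flagged through
    per-parameter split-R̂ (warning above 1.1, the usual rule of thumb).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"design matrix rows ({X.shape}) must match responses ({y.size})")
    if X.shape[1] != spec.degree:
        raise ValueError(f"design has {X.shape[1]} columns but spec degree is {spec.degree}")
    if ((y <= 0) | (y >= 1)).any():
        raise BoundaryResponseError(
            "responses on the boundary {0,1}; apply boundary_adjust before fitting")

    logpost = _make_log_posterior(spec, X, y)
    all_draws = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=mcmc.seed, spawn_key=(c,)))
        theta0 = _initial_theta(spec, X, y, rng)
        all_draws.append(_run_chain(logpost, theta0, mcmc, rng))
    theta = np.stack(all_draws)                      # (chains, iterations, dim)
    theta[..., -1] = np.exp(theta[..., -1])          # log phi -> phi

    names = ["alpha"] + [f"beta{k + 1}" for k in range(spec.degree)] + ["phi"]
    samples = {p: theta[:, :, j] for j, p in enumerate(names)}
    rhat = {p: _split_rhat(samples[p]) for p in names}
    bad = {p: r for p, r in rhat.items() if not (r <= _RHAT_LIMIT)}
    if bad:
        logger.warning("convergence flagged (split-R̂ > %.2f): %s", _RHAT_LIMIT,
                       {p: round(r, 3) for p, r in bad.items()})

    fit = PosteriorFit(
        model=spec, samples=samples, deviance=np.nan, n_iterations=mcmc.iterations,
        rhat=rhat, seed=mcmc.seed,
        standardization=standardization or Standardization(enabled=False),
        x_range=x_range, X=X, y=y, taxon=taxon, o_half=o_half,
    )
    fit.deviance = deviance(fit)
    return fit


def deviance(fit: PosteriorFit, X: np.ndarray | None = None, y: np.ndarray | None = None,
             method: str = "plugin") -> float:
    """Model deviance D = -2 log L.

    ``plugin`` (default) evaluates the likelihood at the posterior means of
    (alpha, beta, phi) — the quantity whose nested differences are judged
    against chi-square quantiles.  ``mean`` instead averages -2 log L over
    the posterior draws.
    """
    X = fit.X if X is None else np.asarray(X, dtype=float)
    y = fit.y if y is None else np.asarray(y, dtype=float)
    if X is None or y is None:
        raise ValueError("deviance needs the design matrix and responses")
    if method == "plugin":
        m = fit.means
        coefs = np.array([m[p] for p in fit.param_names[:-1]])
        eta = coefs[0] + (X @ coefs[1:] if X.shape[1] else 0.0)
        return -2.0 * beta_loglik(y, expit(eta), m["phi"])
    if method == "mean":
        names = fit.param_names
        thetas = np.column_stack([fit.flat(p) for p in names])
        lls = np.empty(thetas.shape[0])
        for i, th in enumerate(thetas):
            eta = th[0] + (X @ th[1:-1] if X.shape[1] else 0.0)
            lls[i] = beta_loglik(y, expit(eta), th[-1])
        return float(-2.0 * lls.mean())
    raise ValueError(f"unknown deviance method {method!r}")


def compare_nested(reduced: PosteriorFit, full: PosteriorFit) -> ModelComparison:
    """Δ-deviance test of a nested pair: improve iff Δ ≥ 3.84 per added parameter."""
    if reduced.model.covariate_name != full.model.covariate_name and reduced.model.degree != 0:
        raise ValueError("models must share the covariate")
    params_added = full.model.degree - reduced.model.degree
    if params_added < 1:
        raise ValueError("full model must add at least one parameter to the reduced model")
    delta = reduced.deviance - full.deviance
    return ModelComparison(
        reduced=reduced.model, full=full.model, delta_deviance=float(delta),
        params_added=params_added,
        improves=bool(delta >= CHI2_CRITICAL_1DF * params_added),
    )


def _plugin_mu(fit: PosteriorFit) -> np.ndarray:
    m = fit.means
    coefs = np.array([m[p] for p in fit.param_names[:-1]])
    eta = coefs[0] + (fit.X @ coefs[1:] if fit.X.shape[1] else 0.0)
    return expit(eta)


def r_squared(fit: PosteriorFit, null_fit: PosteriorFit) -> float:
    """Percent of deviance explained relative to the intercept-only model.

    Computed as R² = 100 (D_null - D_model) / D_null on GLM-style deviances
    measured from the saturated model (mu_i = y_i) at a common precision,
    the fitted model's posterior-mean phi; equivalently, the fraction of the
    null-to-saturated log-likelihood gap the model closes.  The common
    saturated reference is what keeps a deviance ratio meaningful for a
    continuous likelihood, whose raw -2 logL is typically negative at
    realistic n; classical GLMs make the same move by computing the null
    deviance at the model's dispersion.  Values are in [0, 100] up to Monte
    Carlo noise; negatives are clamped to 0 with a warning.
    """
    if fit.y is None or null_fit.y is None:
        raise ValueError("fits do not retain their responses")
    y = fit.y
    phi = fit.means["phi"]
    ll_model = beta_loglik(y, _plugin_mu(fit), phi)
    ll_null = beta_loglik(y, _plugin_mu(null_fit), phi)
    ll_sat = beta_saturated_loglik(y, phi)
    d_null = 2.0 * (ll_sat - ll_null)
    if d_null == 0:
        raise ZeroDivisionError("null deviance is zero; R² undefined")
    raw = 100.0 * 2.0 * (ll_model - ll_null) / d_null
    if raw < 0:
        warnings.warn(f"negative deviance-R² ({raw:.3f}%) clamped to 0", stacklevel=2)
        return 0.0
    return float(raw)


def select_model(
    null_fit: PosteriorFit,
    linear_fit: PosteriorFit,
    quadratic_fit: PosteriorFit,
) -> ModelSelection:
    """Stepwise-forward nested selection: null → linear → quadratic.

    The linear term is accepted only if it improves on the null by the
    Δ-deviance criterion; the quadratic term is then considered only against
    an accepted linear model, so a quadratic can never be chosen when the
    linear term was rejected.
    """
    c1 = compare_nested(null_fit, linear_fit)
    comparisons = [c1]
    chosen = null_fit
    if c1.improves:
        chosen = linear_fit
        c2 = compare_nested(linear_fit, quadratic_fit)
        comparisons.append(c2)
        if c2.improves:
            chosen = quadratic_fit
    for c in comparisons:
        fit = {1: linear_fit, 2: quadratic_fit}[c.full.degree]
        c.r_squared_full = r_squared(fit, null_fit)
    return ModelSelection(chosen=chosen, comparisons=comparisons)


def fitted_curve(fit: PosteriorFit, x_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mean ignorance curve mu(x) over original-unit covariate values.

    Points outside the observed covariate range are evaluated but logged as
    extrapolation.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if fit.x_range is not None:
        lo, hi = fit.x_range
        n_out = int(((x_grid < lo) | (x_grid > hi)).sum())
        if n_out:
            logger.info("fitted_curve: %d of %d points outside the observed range [%g, %g]",
                        n_out, x_grid.size, lo, hi)
    alpha, b1, b2 = fit.coefficients()
    z = fit.standardization.transform(x_grid)
    return x_grid, expit(alpha + b1 * z + b2 * z ** 2)


def fit_covariate_models(
    y: np.ndarray,
    x: np.ndarray,
    mcmc: MCMCSettings,
    covariate_name: str = "",
    standardize: bool = True,
    taxon: str = "",
    o_half: float | None = None,
    **spec_kwargs,
) -> tuple[dict[int, PosteriorFit], ModelSelection]:
    """Fit null/linear/quadratic models for one covariate and select among them.

    Convenience wrapper used by the pipeline: shares the covariate's
    standardisation across degrees and staggers the chain seeds so the three
    fits are independent but jointly reproducible.
    """
    x = np.asarray(x, dtype=float)
    x_range = (float(x.min()), float(x.max()))
    fits: dict[int, PosteriorFit] = {}
    for degree in (0, 1, 2):
        spec = ModelSpec(covariate_name=covariate_name, degree=degree,
                         standardize=standardize, **spec_kwargs)
        X, std = build_design(x, degree, standardize=standardize)
        fits[degree] = sample_posterior(
            spec, X, y,
            MCMCSettings(iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                         chains=mcmc.chains, seed=mcmc.seed + degree,
                         adapt_interval=mcmc.adapt_interval),
            standardization=std, x_range=x_range, taxon=taxon, o_half=o_half,
        )
    return fits, select_model(fits[0], fits[1], fits[2])
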