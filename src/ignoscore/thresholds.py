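"""Covariate thresholds where the fitted ignorance curve crosses a target score.

With O_0.5 = 1, ignorance 0.5 marks the point where at least one recorder is
effectively present; the covariate value at which a fitted curve crosses 0.5
is therefore an interpretable "threshold" of accessibility or population
needed for a taxon to start being recorded.

On the logit scale the crossing condition alpha + beta1 x* + beta2 x*^2 =
logit(target) is a polynomial in the standardised coordinate x*, so roots
are solved in closed form (for target 0.5 the right-hand side is exactly 0)
and back-transformed to original units.  A dense grid scan of the fitted
curve provides an independent numerical cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ignoscore.beta_glm import PosteriorFit, Standardization, fitted_curve

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    """Crossings of one fitted curve through one target ignorance score."""

    covariate_name: str
    target_score: float
    crossings: list[float] = field(default_factory=list)       # original units, ascending
    directions: list[str] = field(default_factory=list)        # "falling" | "rising"
    in_observed_range: list[bool] = field(default_factory=list)
    degenerate: bool = False


def _direction(beta1: float, beta2: float, z: float) -> str:
    """Sign of d(mu)/dx at a standardised root (mu is increasing in eta)."""
    slope = beta1 + 2.0 * beta2 * z
    if slope < 0:
        return "falling"
    if slope > 0:
        return "rising"
    # tangency: classify by curvature (curve touches the target from one side)
    return "falling" if beta2 > 0 else "rising"


def crossing_points(
    alpha: float,
    beta1: float,
    beta2: float | None,
    target: float,
    x_range: tuple[float, float],
    standardization: Standardization | None = None,
    covariate_name: str = "",
) -> ThresholdResult:
    """Closed-form covariate values where mu(x) equals the target score.

    Solves alpha + beta1 x* + beta2 x*^2 = logit(target) for the standardised
    coordinate (one root for linear fits, 0–2 real roots for quadratics),
    back-transforms roots to original units, and flags roots outside the
    observed covariate range.  A constant curve (beta1 = beta2 = 0) is
    degenerate: no crossings, with a warning, even if it sits exactly on the
    target.
    """
    if not 0 < target < 1:
        raise ValueError(f"target score must be in (0, 1), got {target}")
    for name, v in (("alpha", alpha), ("beta1", beta1)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    std = standardization or Standardization(enabled=False)
    b2 = 0.0 if beta2 is None else float(beta2)
    c = float(logit(target))  # exactly 0 for target 0.5

    result = ThresholdResult(covariate_name=covariate_name, target_score=float(target))
    if beta1 == 0.0 and b2 == 0.0:
        warnings.warn("constant fitted curve: no threshold crossings", stacklevel=2)
        result.degenerate = True
        return result

    if b2 == 0.0:
        roots = [(c - alpha) / beta1]
    else:
        disc = beta1 ** 2 - 4.0 * b2 * (alpha - c)
        if disc < 0:
            roots = []
        elif disc == 0:
            roots = [-beta1 / (2.0 * b2)]
        else:
            sq = np.sqrt(disc)
            roots = [(-beta1 - sq) / (2.0 * b2), (-beta1 + sq) / (2.0 * b2)]

    lo, hi = x_range
    for z in sorted(roots):
        x = float(std.inverse(np.array(z)))
        result.crossings.append(x)
        result.directions.append(_direction(beta1, b2, z))
        result.in_observed_range.append(bool(lo <= x <= hi))
    return result


def grid_scan_crossings(
    fit: PosteriorFit, target: float, n_points: int = 4001
) -> list[float]:
    """Numerical crossings from a dense scan of the fitted curve (oracle path).

    Brackets every sign change of mu(x) - target over the observed range and
    refines each with Brent's method.  Used to cross-check the analytic roots.
    """
    lo, hi = fit.x_range if fit.x_range is not None else (-5.0, 5.0)
    xs = np.linspace(lo, hi, n_points)
    _, mu = fitted_curve(fit, xs)
    f = mu - target
    roots = []
    sign_change = np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)
    alpha, b1, b2 = fit.coefficients()

    def g(x: float) -> float:
        z = fit.standardization.transform(np.array(x))
        return float(expit(alpha + b1 * z + b2 * z ** 2) - target)

    for i in sign_change:
        roots.append(brentq(g, xs[i], xs[i + 1], xtol=1e-12))
    roots.extend(float(x) for x in xs[f == 0.0])
    return sorted(roots)


def _threshold_interval(
    fit: PosteriorFit, target: float, point: float, n_draws: int = 1000
) -> tuple[float, float]:
    """95% posterior interval of one crossing, via per-draw closed-form roots.

    For each thinned posterior draw the root nearest the point-estimate
    crossing is taken; draws with no real root are skipped.  This interval is
    an extension beyond point-value thresholds and is labelled as such in the
    report.
    """
    names = fit.param_names
    draws = np.column_stack([fit.flat(p) for p in names])
    if draws.shape[0] > n_draws:
        idx = np.linspace(0, draws.shape[0] - 1, n_draws).astype(int)
        draws = draws[idx]
    c = float(logit(target))
    roots = []
    for th in draws:
        a = th[0]
        b1 = th[1] if fit.model.degree >= 1 else 0.0
        b2 = th[2] if fit.model.degree >= 2 else 0.0
        if b2 == 0.0:
            if b1 == 0.0:
                continue
            cand = [(c - a) / b1]
        else:
            disc = b1 ** 2 - 4.0 * b2 * (a - c)
            if disc < 0:
                continue
            sq = np.sqrt(disc)
            cand = [(-b1 - sq) / (2.0 * b2), (-b1 + sq) / (2.0 * b2)]
        xs = fit.standardization.inverse(np.array(cand))
        roots.append(float(xs[np.argmin(np.abs(xs - point))]))
    if len(roots) < 20:
        return (np.nan, np.nan)
    return (float(np.percentile(roots, 2.5)), float(np.percentile(roots, 97.5)))


def threshold_report(
    fits: list[PosteriorFit],
    target: float = 0.5,
    check_tol: float = 1e-6,
    posterior_intervals: bool = True,
) -> pd.DataFrame:
    """Threshold table across fits (taxa × covariates × O_0.5 values).

    One row per crossing (or a single empty-crossing row when a curve never
    spans the target).  Analytic roots are verified against the dense
    grid-scan oracle; disagreement beyond ``check_tol`` in fitted-curve units
    raises.
    """
    rows = []
    for fit in fits:
        alpha, b1, b2 = fit.coefficients()
        res = crossing_points(alpha, b1, b2 if fit.model.degree >= 2 else None,
                              target, fit.x_range or (0.0, 1.0),
                              fit.standardization, fit.model.covariate_name)
        scan = grid_scan_crossings(fit, target)
        in_range = [x for x, ok in zip(res.crossings, res.in_observed_range) if ok]
        if len(in_range) != len(scan) and not res.degenerate:
            # scan can only miss tangencies; any other mismatch is a defect
            non_tangent = [x for x in in_range
                           if abs(b1 + 2 * b2 * fit.standardization.transform(np.array(x))) > 1e-9]
            if len(non_tangent) != len(scan):
                raise AssertionError(
                    f"analytic/grid-scan crossing mismatch for {fit.model.covariate_name}: "
                    f"{in_range} vs {scan}")
            in_range = non_tangent
        for x_a, x_s in zip(in_range, scan):
            _, mu_a = fitted_curve(fit, np.array([x_a]))
            _, mu_s = fitted_curve(fit, np.array([x_s]))
            if abs(mu_a[0] - mu_s[0]) > check_tol:
                raise AssertionError("analytic and grid-scan roots disagree beyond tolerance")
        base = {"taxon": fit.taxon, "covariate": fit.model.covariate_name,
                "o_half": fit.o_half, "target": target, "degree": fit.model.degree}
        if not res.crossings:
            rows.append({**base, "crossing": np.nan, "lo95": np.nan, "hi95": np.nan,
                         "direction": "", "in_range": False})
        for x, d, ok in zip(res.crossings, res.directions, res.in_observed_range):
            lo95, hi95 = (_threshold_interval(fit, target, x)
                          if posterior_intervals else (np.nan, np.nan))
            rows.append({**base, "crossing": x, "lo95": lo95, "hi95": hi95,
                         "direction": d, "in_range": ok})
    return pd.DataFrame(rows)
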