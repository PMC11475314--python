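"""Recover exchange and growth rates (with standard errors) from time courses.

Exchange rates: with the growth rate mu and initial biomass BM_0 treated as
known, the exponential-phase model

    [i](t) = [i]_0 + q * g(t),   g(t) = BM_0 / mu * (exp(mu t) - 1)

is linear in its two free parameters ([i]_0, q).  Ordinary (unweighted)
least squares over all replicate measurements jointly therefore has a closed
form, and the asymptotic covariance s^2 (X^T X)^-1 at the optimum — the same
quantity an iterative nonlinear fitter reports — is exact.  The fit is
deliberately unweighted even though the simulated noise is heteroscedastic,
matching the default behavior of standard nonlinear-least-squares tooling;
inverse-variance weighting is available behind a flag.

Growth rates: BM(t) = BM_0 exp(mu t) is genuinely nonlinear and is fitted
with Levenberg-Marquardt, started from the log-linear regression estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from fluxprop.simulate import BiomassSeries, ConcentrationProfile

_XTOL = 1e-8
_MAXFEV = 200


@dataclass(frozen=True)
class RateFit:
    """Fitted exchange rate for one metabolite (one Monte-Carlo draw)."""

    metabolite: str
    q_hat: float | None
    se_q: float | None
    i0_hat: float | None
    converged: bool
    residual_variance: float | None = None


@dataclass(frozen=True)
class GrowthFit:
    """Fitted exponential growth parameters."""

    mu_hat: float | None
    bm0_hat: float | None
    se_mu: float | None
    converged: bool


def growth_factor(times: np.ndarray, mu: float, bm0: float) -> np.ndarray:
    """g(t) = BM_0/mu (exp(mu t) - 1): cumulative biomass per unit rate."""
    return bm0 / mu * (np.exp(mu * np.asarray(times, dtype=float)) - 1.0)


def fit_rates_batch(
    values: np.ndarray, times: np.ndarray, bm0: float, mu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of the rate model over stacked draws.

    ``values`` has shape (..., n_replicates, n_times); all leading axes are
    treated as independent fits sharing the same design (same schedule, mu
    and BM_0).  Returns (q_hat, se_q, i0_hat, s2) with the leading shape of
    ``values``.  Entries are NaN (and should be treated as non-converged)
    only if the design or data are degenerate.
    """
    times = np.asarray(times, dtype=float)
    if np.unique(times).size < 3:
        raise ValueError("rate fitting needs at least 3 distinct time points")
    lead = values.shape[:-2]
    n_rep, n_t = values.shape[-2:]
    g = growth_factor(times, mu, bm0)
    x = np.column_stack([np.ones(n_rep * n_t), np.tile(g, n_rep)])  # (N, 2)
    y = values.reshape(-1, n_rep * n_t).T  # (N, n_fits)
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ y)  # (2, n_fits)
    resid = y - x @ beta
    dof = n_rep * n_t - 2
    s2 = (resid ** 2).sum(axis=0) / dof
    se_q = np.sqrt(s2 * xtx_inv[1, 1])
    i0_hat = beta[0].reshape(lead)
    q_hat = beta[1].reshape(lead)
    return q_hat, se_q.reshape(lead), i0_hat, s2.reshape(lead)


def fit_rate(
    profile: ConcentrationProfile, bm0: float, mu: float, weighted: bool = False
) -> RateFit:
    """Fit (q, [i]_0) to one replicate x time profile; mu and BM_0 fixed.

    Non-convergence (degenerate data) is reported through the ``converged``
    flag, not raised; a schedule with fewer than 3 distinct time points is an
    input error.
    """
    values = np.asarray(profile.values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    times = np.asarray(profile.times, dtype=float)
    if np.unique(times).size < 3:
        raise ValueError("rate fitting needs at least 3 distinct time points")
    try:
        if weighted:
            q, se, i0, s2 = _fit_weighted(values, times, bm0, mu)
        else:
            q, se, i0, s2 = fit_rates_batch(values[None, ...], times, bm0, mu)
            q, se, i0, s2 = float(q[0]), float(se[0]), float(i0[0]), float(s2[0])
    except np.linalg.LinAlgError:
        return RateFit(profile.metabolite, None, None, None, converged=False)
    if not (math.isfinite(q) and math.isfinite(se)):
        return RateFit(profile.metabolite, None, None, None, converged=False)
    return RateFit(profile.metabolite, q, se, i0, converged=True, residual_variance=s2)


def _fit_weighted(values, times, bm0, mu):
    """One-step reweighted LS: weights 1/ideal^2 from the OLS fit."""
    q0, _, i00, _ = fit_rates_batch(values[None, ...], times, bm0, mu)
    g = growth_factor(times, mu, bm0)
    ideal = i00[0] + q0[0] * g
    w = 1.0 / np.maximum(np.abs(ideal), 1e-12)
    n_rep = values.shape[0]
    x = np.column_stack([np.ones(values.size), np.tile(g, n_rep)])
    y = values.reshape(-1)
    wv = np.tile(w, n_rep)
    xw = x * wv[:, None]
    yw = y * wv
    xtx_inv = np.linalg.inv(xw.T @ xw)
    beta = xtx_inv @ (xw.T @ yw)
    resid = yw - xw @ beta
    s2 = float((resid ** 2).sum() / (y.size - 2))
    se_q = math.sqrt(s2 * xtx_inv[1, 1])
    return float(beta[1]), se_q, float(beta[0]), s2


def fit_growth(series: BiomassSeries) -> GrowthFit:
    """Fit BM_0 exp(mu t) to a biomass series; asymptotic SEs from curve_fit."""
    times = np.asarray(series.times, dtype=float)
    values = np.asarray(series.values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if np.unique(times).size < 3:
        raise ValueError("growth fitting needs at least 3 distinct time points")
    if not np.any(values > 0):
        return GrowthFit(None, None, None, converged=False)

    n_rep = values.shape[0]
    t_all = np.tile(times, n_rep)
    y_all = values.reshape(-1)
    pos = y_all > 0
    # log-linear start values
    slope, intercept = np.polyfit(t_all[pos], np.log(y_all[pos]), 1)
    p0 = (math.exp(intercept), max(slope, 1e-4))
    try:
        popt, pcov = curve_fit(
            lambda t, bm0, mu: bm0 * np.exp(mu * t),
            t_all, y_all, p0=p0, maxfev=_MAXFEV, xtol=_XTOL, ftol=_XTOL,
        )
    except (RuntimeError, ValueError):
        return GrowthFit(None, None, None, converged=False)
    bm0_hat, mu_hat = float(popt[0]), float(popt[1])
    se_mu = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else None
    if not (mu_hat > 0 and math.isfinite(mu_hat)):
        return GrowthFit(None, None, None, converged=False)
    return GrowthFit(mu_hat, bm0_hat, se_mu, converged=True)


def rse(fit: RateFit) -> float:
    """Relative standard error SE(q)/|q| of a converged rate fit."""
    if not fit.converged:
        raise ValueError(f"{fit.metabolite}: fit did not converge; RSE undefined")
    if fit.q_hat == 0:
        raise ZeroDivisionError(f"{fit.metabolite}: q_hat is 0; RSE undefined")
    return fit.se_q / abs(fit.q_hat)
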