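"""Individual MAP Bayesian estimation and Laplace population fitting.

The individual objective is the exact -2 log of (Gaussian proportional-error
likelihood x lognormal random-effect prior); the population objective sums
per-subject Laplace approximations of the marginal likelihood over the single
EC50 random effect.  Only the PD covariate side is estimable (the two
per-allele EC50s, covariate coefficients on EC50, omega, sigma); all PK
parameters and the transit/INR scale parameters stay fixed at their published
values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .engine import (
    CovariateTerm,
    PreparedCohort,
    cohort_objectives,
    final_model_terms,
    laplace_components,
    map_etas,
)
from .model_core import (
    DEFAULT_THETA,
    PatientRecord,
    ThetaVector,
    individual_ec50,
    inr_trajectory,
    typical_ec50,
)

__all__ = [
    "EtaEstimate", "FitResult", "individual_objective", "map_estimate",
    "population_ofv", "fit_population", "cwres",
]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

# parameters estimated in the published final model
DEFAULT_ESTIMATE = ("ec50_g", "ec50_a", "beta_weight", "beta_cm1",
                    "omega", "sigma")

_LOG_LO, _LOG_HI = -5.0, 5.0  # bounds for log-scale parameters
_COEF_LO, _COEF_HI = -50.0, 50.0


@dataclass
class EtaEstimate:
    """MAP-estimated individual deviation of log EC50."""

    eta_hat: float
    objective: float
    converged: bool
    n_obs: int


@dataclass
class FitResult:
    """Population fit: estimates, OFV, convergence and uncertainty."""

    theta_hat: ThetaVector
    terms: tuple  # CovariateTerm sequence with fitted coefficients
    omega_hat: float
    sigma_hat: float
    ofv: float
    converged: bool
    params: dict = field(default_factory=dict)  # name -> estimate
    se: dict = field(default_factory=dict)
    rse_percent: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    n_iter: int = 0
    boundary_hits: tuple = ()
    eta_hat: Optional[np.ndarray] = None


def _obs_arrays(patient: PatientRecord):
    t = patient.obs_times
    y = patient.obs_values
    keep = (t > 0) & np.isfinite(y)
    return t[keep], y[keep]


def individual_objective(patient: PatientRecord, eta: float,
                         theta: ThetaVector = DEFAULT_THETA,
                         omega: float = 0.558, sigma: float = 0.365,
                         dt: float = 0.5) -> float:
    """-2 log(posterior) up to the marginal constant:

        sum_obs [ (y-f)^2/(sigma f)^2 + ln(2 pi (sigma f)^2) ]
        + eta^2/omega^2 + ln(2 pi omega^2)
    """
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    t, y = _obs_arrays(patient)
    prior = eta ** 2 / omega ** 2 + np.log(2.0 * np.pi * omega ** 2)
    if t.size == 0:
        return float(prior)
    f = inr_trajectory(patient, eta, theta, times=t, dt=dt).inr
    if np.any(f <= 0):
        raise FloatingPointError("non-positive INR prediction")
    sf2 = (sigma * f) ** 2
    return float(np.sum((y - f) ** 2 / sf2 + np.log(2.0 * np.pi * sf2)) + prior)


def map_estimate(patient: PatientRecord, theta: ThetaVector = DEFAULT_THETA,
                 omega: float = 0.558, sigma: float = 0.365,
                 dt: float = 0.5) -> EtaEstimate:
    """MAP eta by bounded scalar minimization, multi-started from {-w, 0, +w}."""
    t, _ = _obs_arrays(patient)

    def obj(e):
        return individual_objective(patient, e, theta, omega, sigma, dt=dt)

    if t.size == 0:
        return EtaEstimate(0.0, obj(0.0), True, 0)

    best = None
    ok = False
    for start in (-omega, 0.0, omega):
        res = minimize_scalar(
            obj, bounds=(start - 5.0 * omega, start + 5.0 * omega),
            method="bounded", options={"xatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    return EtaEstimate(float(best.x), float(best.fun), ok, int(t.size))


def _prepare(cohort, theta, dt) -> PreparedCohort:
    if isinstance(cohort, PreparedCohort):
        return cohort
    return PreparedCohort(cohort, theta, dt=dt)


def population_ofv(cohort, theta: ThetaVector = DEFAULT_THETA,
                   omega: float = 0.558, sigma: float = 0.365,
                   terms: Optional[Sequence[CovariateTerm]] = None,
                   dt: float = 1.0) -> float:
    """Laplace-approximate -2 log marginal likelihood summed over subjects."""
    prep = _prepare(cohort, theta, dt)
    if terms is None:
        terms = final_model_terms(theta)
    ofv_i, _, bad = laplace_components(
        prep, theta.ec50_g, theta.ec50_a, terms, omega, sigma)
    if np.any(bad):
        warnings.warn(f"non-positive eta curvature for {int(bad.sum())} "
                      "subject(s); prior curvature used", RuntimeWarning)
    return float(np.sum(ofv_i))


def _pack_names(terms: Sequence[CovariateTerm]):
    return ["ec50_g", "ec50_a"] + [f"beta_{t.covariate}" for t in terms] + \
        ["omega", "sigma"]


def _is_log_scale(name: str) -> bool:
    return name in ("ec50_g", "ec50_a", "omega", "sigma")


def fit_population(cohort, theta: ThetaVector = DEFAULT_THETA,
                   terms: Optional[Sequence[CovariateTerm]] = None,
                   estimate: Sequence[str] = DEFAULT_ESTIMATE,
                   init: Optional[dict] = None,
                   tol: float = 1e-6, maxiter: int = 4000,
                   compute_rse: bool = True, dt: float = 1.0,
                   effort: str = "full") -> FitResult:
    """Fit the estimable parameters by Nelder-Mead on the Laplace OFV.

    Positive parameters are optimized on the log scale; covariate coefficients
    (power exponents, additive shifts) on the natural scale.  ``estimate``
    selects which of {ec50_g, ec50_a, beta_<covariate>, omega, sigma} move;
    everything else stays fixed at its initial value.  ``init`` overrides the
    starting values by name (coefficients default to the values carried by
    ``terms``; omega/sigma default to 0.5/0.3).

    ``effort`` "full" runs the simplex twice (restart from the incumbent) with
    tight tolerances; "fast" runs it once from a small warm-start simplex,
    intended for refits close to a known solution (bootstrap replicates,
    candidate steps in stepwise selection).
    """
    prep = _prepare(cohort, theta, dt)
    if terms is None:
        terms = final_model_terms(theta)
    terms = tuple(terms)
    prep.warm_covariates(terms)

    names = _pack_names(terms)
    unknown = set(estimate) - set(names)
    if unknown:
        raise ValueError(f"cannot estimate unknown parameter(s): {sorted(unknown)}")

    values = {"ec50_g": theta.ec50_g, "ec50_a": theta.ec50_a,
              "omega": 0.5, "sigma": 0.3}
    for t in terms:
        values[f"beta_{t.covariate}"] = t.coef
    if init:
        values.update(init)

    free = [n for n in names if n in estimate]
    boundary_hits = []

    def pack(vals: dict) -> np.ndarray:
        x = []
        for n in free:
            v = vals[n]
            x.append(np.log(v) if _is_log_scale(n) else v)
        return np.asarray(x, dtype=float)

    def unpack(x: np.ndarray) -> dict:
        vals = dict(values)
        for n, xi in zip(free, x):
            if _is_log_scale(n):
                xc = float(np.clip(xi, _LOG_LO, _LOG_HI))
                if xc != xi and n not in boundary_hits:
                    boundary_hits.append(n)
                vals[n] = float(np.exp(xc))
            else:
                xc = float(np.clip(xi, _COEF_LO, _COEF_HI))
                if xc != xi and n not in boundary_hits:
                    boundary_hits.append(n)
                vals[n] = xc
        return vals

    def ofv_of(vals: dict) -> float:
        cur_terms = tuple(t.with_coef(vals[f"beta_{t.covariate}"]) for t in terms)
        ofv_i, _, _ = laplace_components(
            prep, vals["ec50_g"], vals["ec50_a"], cur_terms,
            vals["omega"], vals["sigma"])
        return float(np.sum(ofv_i))

    def fun(x):
        return ofv_of(unpack(x))

    x0 = pack(values)
    f0 = fun(x0)
    n_iter = 0
    converged = True
    if free and effort == "fast":
        step = np.where([_is_log_scale(n) for n in free], 0.08, 0.05)
        simplex = np.vstack([x0] + [x0 + step * e
                                    for e in np.eye(len(free))])
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4,
                                "fatol": 1e-5 * max(1.0, abs(f0)),
                                "initial_simplex": simplex,
                                "maxiter": maxiter, "maxfev": maxiter})
        n_iter = res.nit
        converged = bool(res.success)
        x_hat, ofv = res.x, float(res.fun)
        if f0 < ofv:
            x_hat, ofv, converged = x0, f0, False
    elif free:
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7 * max(1.0, abs(f0)),
                                "maxiter": maxiter, "maxfev": maxiter})
        n_iter = res.nit
        # one restart from the incumbent; declares convergence when the
        # restart cannot improve the OFV by more than tol (relative)
        res2 = minimize(fun, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-6,
                                 "fatol": 1e-7 * max(1.0, abs(res.fun)),
                                 "maxiter": maxiter, "maxfev": maxiter})
        n_iter += res2.nit
        best = res2 if res2.fun <= res.fun else res
        converged = abs(res.fun - res2.fun) <= tol * max(1.0, abs(res2.fun)) \
            and bool(res.success or res2.success)
        x_hat = best.x
        ofv = float(min(best.fun, f0))
        if f0 < best.fun:  # optimizer failed to beat the start; keep start
            x_hat = x0
            converged = False
    else:
        x_hat, ofv = x0, f0

    vals_hat = unpack(x_hat)
    for n in free:  # flag estimates resting on (or hugging) a bound
        if _is_log_scale(n) and n not in boundary_hits:
            if np.log(vals_hat[n]) <= _LOG_LO + 1e-2 or \
                    np.log(vals_hat[n]) >= _LOG_HI - 1e-2:
                boundary_hits.append(n)
    fitted_terms = tuple(t.with_coef(vals_hat[f"beta_{t.covariate}"])
                         for t in terms)
    theta_updates = {"ec50_g": vals_hat["ec50_g"], "ec50_a": vals_hat["ec50_a"]}
    for t in fitted_terms:
        if t.kind == "power" and t.covariate == "weight":
            theta_updates["theta_wt"] = t.coef
        if t.kind == "shift" and t.covariate == "cm1":
            theta_updates["theta_cm1"] = t.coef
    theta_hat = prep.theta.with_updates(**theta_updates)

    eta_hat = map_etas(prep, vals_hat["ec50_g"], vals_hat["ec50_a"],
                       fitted_terms, vals_hat["omega"], vals_hat["sigma"])

    result = FitResult(
        theta_hat=theta_hat, terms=fitted_terms,
        omega_hat=vals_hat["omega"], sigma_hat=vals_hat["sigma"],
        ofv=ofv, converged=converged,
        params={n: vals_hat[n] for n in free},
        n_iter=int(n_iter), boundary_hits=tuple(boundary_hits),
        eta_hat=eta_hat,
    )
    if boundary_hits:
        warnings.warn(f"parameter(s) at bounds: {boundary_hits}", RuntimeWarning)

    if compute_rse and free:
        se = _hessian_se(ofv_of, vals_hat, free, x_hat)
        for n in free:
            result.se[n] = se.get(n, np.nan)
            est = vals_hat[n]
            result.rse_percent[n] = 100.0 * se.get(n, np.nan) / abs(est) \
                if est != 0 else np.nan
            result.ci95[n] = (est - 1.96 * result.se[n],
                              est + 1.96 * result.se[n])
    return result


def _hessian_se(ofv_of, vals: dict, free: Sequence[str],
                x_hat: np.ndarray) -> dict:
    """Standard errors from the numerical OFV Hessian.

    The Hessian is taken on the optimizer's (log-transformed) scale, where the
    objective is better conditioned, and mapped back by the delta method;
    Cov = 2 H^-1 since the OFV is -2 log L.
    """
    p = len(free)
    x0 = np.asarray(x_hat, dtype=float)
    h = np.full(p, 0.02)

    def f(x):
        cur = dict(vals)
        for n, xi in zip(free, x):
            cur[n] = float(np.exp(xi)) if _is_log_scale(n) else float(xi)
        return ofv_of(cur)

    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    if w[-1] <= 0:
        warnings.warn("OFV Hessian has no positive curvature; SEs unavailable",
                      RuntimeWarning)
        return {}
    if w[0] <= 0:
        # near-flat or noise-corrupted directions: clip eigenvalues, which
        # inflates (never understates) the uncertainty in those directions
        warnings.warn("OFV Hessian not positive definite; flat directions "
                      "regularized, affected SEs are conservative",
                      RuntimeWarning)
        w = np.maximum(w, 1e-4 * w[-1])
    cov = 2.0 * (V / w) @ V.T
    se_t = np.sqrt(np.diag(cov))
    # delta method back to the natural scale for log parameters
    return {n: float(se_t[i] * (vals[n] if _is_log_scale(n) else 1.0))
            for i, n in enumerate(free)}


def cwres(cohort, fit: FitResult, theta: Optional[ThetaVector] = None,
          omega: Optional[float] = None, sigma: Optional[float] = None,
          dt: float = 1.0, outlier_threshold: float = 6.0):
    """Conditional weighted residuals.

    The model is linearized in eta at the MAP estimate:  E[y] ~ f(eta_hat) -
    g*eta_hat with g = df/deta, Var[y] ~ g w^2 g' + diag((sigma f)^2); CWRES is
    the Cholesky-whitened residual.  Returns (values, outlier_mask) with
    outliers at |CWRES| > ``outlier_threshold`` (the diagnostic convention used
    for this model family).
    """
    theta = theta if theta is not None else fit.theta_hat
    omega = omega if omega is not None else fit.omega_hat
    sigma = sigma if sigma is not None else fit.sigma_hat
    prep = _prepare(cohort, theta, dt)
    terms = fit.terms
    prep.warm_covariates(terms)

    eta_hat = map_etas(prep, theta.ec50_g, theta.ec50_a, terms, omega, sigma)
    typ = prep.typical_ec50s(theta.ec50_g, theta.ec50_a, terms)
    h = 1e-4
    f = prep.predict_obs(typ * np.exp(eta_hat))
    f_plus = prep.predict_obs(typ * np.exp(eta_hat + h))
    f_minus = prep.predict_obs(typ * np.exp(eta_hat - h))
    g = (f_plus - f_minus) / (2 * h)

    values = np.empty(prep.m)
    for i in range(prep.n):
        sl = slice(prep.starts[i], prep.starts[i + 1])
        gi = g[sl]
        fi = f[sl]
        resid = prep.y[sl] - (fi - gi * eta_hat[i])
        V = omega ** 2 * np.outer(gi, gi) + np.diag((sigma * fi) ** 2)
        L = np.linalg.cholesky(V)
        values[sl] = np.linalg.solve(L, resid)
    return values, np.abs(values) > outlier_threshold
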