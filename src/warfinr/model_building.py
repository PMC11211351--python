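"""Covariate screening, stepwise selection and bootstrap validation.

Screening associates empirical-Bayes eta estimates from the covariate-free
model with candidate covariates (rank correlation for continuous candidates,
rank-sum comparison for binary flags).  Stepwise selection is greedy forward
inclusion on the Laplace OFV at dOFV > 3.84 (chi-square, df=1, alpha=0.05)
followed by backward elimination at dOFV > 6.63 (alpha=0.01) — the standard
pharmacometric thresholds.  Bootstrap validation resamples subjects with
replacement and refits, reporting medians and 2.5-97.5% percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .engine import CovariateTerm, PreparedCohort, map_etas
from .estimation import FitResult, fit_population
from .model_core import DEFAULT_THETA, ThetaVector

__all__ = [
    "ScreenRow", "CovariateScreenReport", "SelectionStep", "SelectionTrace",
    "BootstrapResult", "screen_covariates", "stepwise_select",
    "bootstrap_validate", "default_candidate_terms",
]

log = logging.getLogger(__name__)

FORWARD_DOFV = 3.84  # chi2(1), alpha = 0.05
BACKWARD_DOFV = 6.63  # chi2(1), alpha = 0.01

DEFAULT_CANDIDATES = ("sex", "age", "weight", "bmi", "cm1", "cm2", "cm3", "cm4")

# covariates modelled as power terms on EC50 (with their centering values);
# everything else is a binary additive shift
_CONTINUOUS_CENTERS = {"weight": 60.0, "age": 60.0, "bmi": 22.0,
                       "height_cm": 160.0}


def default_candidate_terms(names: Sequence[str] = DEFAULT_CANDIDATES) -> dict:
    """Candidate covariate terms on EC50, keyed by covariate name."""
    out = {}
    for name in names:
        if name in _CONTINUOUS_CENTERS:
            out[name] = CovariateTerm("power", name,
                                      center=_CONTINUOUS_CENTERS[name])
        else:
            out[name] = CovariateTerm("shift", name)
    return out


@dataclass
class ScreenRow:
    covariate: str
    kind: str  # "continuous" | "binary" | "excluded"
    statistic: float
    p_value: float
    selected: bool
    note: str = ""


@dataclass
class CovariateScreenReport:
    rows: list
    alpha: float

    def selected(self, prefer_weight_over_bmi: bool = True) -> list:
        """Names passing the screen; when both weight and BMI pass, weight is
        kept and BMI dropped (body weight is the clinically simpler measure)."""
        names = [r.covariate for r in self.rows if r.selected]
        if prefer_weight_over_bmi and "weight" in names and "bmi" in names:
            names.remove("bmi")
        return names


@dataclass
class SelectionStep:
    action: str  # "add" | "remove" | "stop"
    covariate: str
    label: str
    ofv: float
    delta_ofv: float


@dataclass
class SelectionTrace:
    steps: list
    final_terms: tuple
    final_fit: Optional[FitResult] = None

    @property
    def final_covariates(self) -> tuple:
        return tuple(t.covariate for t in self.final_terms)


@dataclass
class BootstrapResult:
    n_requested: int
    n_success: int
    medians: dict
    q025: dict
    q975: dict
    original: dict
    samples: dict = field(default_factory=dict)

    def ci(self, name: str) -> tuple:
        return (self.q025[name], self.q975[name])


def _binary_like(x: np.ndarray) -> bool:
    return np.unique(x).size == 2


def screen_covariates(cohort, base_fit: FitResult,
                      candidates: Sequence[str] = DEFAULT_CANDIDATES,
                      alpha: float = 0.05, dt: float = 1.0) -> CovariateScreenReport:
    """Associate eta_hat under the covariate-free model with each candidate.

    ``base_fit`` must come from a fit with no EC50 covariate terms; its
    parameter estimates define the model under which the etas are computed.
    """
    if base_fit.terms:
        raise ValueError("base_fit must be a covariate-free model fit")
    if not base_fit.converged:
        raise ValueError("base_fit did not converge")
    theta = base_fit.theta_hat
    prep = cohort if isinstance(cohort, PreparedCohort) \
        else PreparedCohort(cohort, theta, dt=dt)
    eta = base_fit.eta_hat
    if eta is None or len(eta) != prep.n:
        eta = map_etas(prep, theta.ec50_g, theta.ec50_a, (),
                       base_fit.omega_hat, base_fit.sigma_hat)

    rows = []
    for name in candidates:
        x = prep.covariate(name)
        if np.unique(x).size < 2:
            rows.append(ScreenRow(name, "excluded", np.nan, np.nan, False,
                                  "constant in cohort"))
            continue
        if _binary_like(x):
            lo, hi = np.unique(x)
            stat, p = stats.ranksums(eta[x == hi], eta[x == lo])
            rows.append(ScreenRow(name, "binary", float(stat), float(p),
                                  bool(p < alpha)))
        else:
            rho, p = stats.spearmanr(eta, x)
            rows.append(ScreenRow(name, "continuous", float(rho), float(p),
                                  bool(p < alpha)))
    return CovariateScreenReport(rows, alpha)


def _fit_terms(prep: PreparedCohort, theta: ThetaVector, terms: tuple,
               init: dict, **fit_kw) -> FitResult:
    estimate = ["ec50_g", "ec50_a"] + \
        [f"beta_{t.covariate}" for t in terms] + ["omega", "sigma"]
    return fit_population(prep, theta, terms=terms, estimate=estimate,
                          init=init, **fit_kw)


def stepwise_select(cohort, theta: ThetaVector = DEFAULT_THETA,
                    candidates: Optional[dict] = None,
                    forward_threshold: float = FORWARD_DOFV,
                    backward_threshold: float = BACKWARD_DOFV,
                    init: Optional[dict] = None, dt: float = 1.0,
                    **fit_kw) -> SelectionTrace:
    """Greedy forward-inclusion / backward-elimination over the Laplace OFV.

    ``candidates`` maps covariate name -> CovariateTerm template (coef is the
    starting value for that coefficient, normally 0 = no effect).  Candidate
    fits that fail to converge are skipped with a log note.
    """
    if candidates is None:
        candidates = default_candidate_terms(("weight", "cm1"))
    prep = cohort if isinstance(cohort, PreparedCohort) \
        else PreparedCohort(cohort, theta, dt=dt)
    fit_kw.setdefault("compute_rse", False)
    fit_kw.setdefault("effort", "fast")

    init = dict(init or {})
    steps = []
    current: tuple = ()
    base_fit = _fit_terms(prep, theta, current, init, **fit_kw)
    cur_ofv = base_fit.ofv
    cur_fit = base_fit
    warm = dict(init)
    warm.update(base_fit.params)
    steps.append(SelectionStep("stop", "", "Base model", cur_ofv, 0.0))

    remaining = dict(candidates)
    while remaining:
        trials = {}
        for name, tmpl in remaining.items():
            terms = current + (tmpl,)
            start = dict(warm)
            start.setdefault(f"beta_{name}", tmpl.coef)
            fit = _fit_terms(prep, theta, terms, start, **fit_kw)
            if not fit.converged:
                log.warning("forward step for %s did not converge; skipped", name)
                continue
            trials[name] = fit
        if not trials:
            break
        name = min(trials, key=lambda k: trials[k].ofv)
        fit = trials[name]
        delta = fit.ofv - cur_ofv
        if delta < -forward_threshold:
            current = current + (remaining.pop(name),)
            current = tuple(
                t.with_coef(fit.params.get(f"beta_{t.covariate}", t.coef))
                for t in current)
            cur_ofv, cur_fit = fit.ofv, fit
            warm.update(fit.params)
            steps.append(SelectionStep(
                "add", name, _label(current), fit.ofv, delta))
        else:
            steps.append(SelectionStep(
                "stop", name, _label(current) + f" + {name} (rejected)",
                fit.ofv, delta))
            break

    while current:
        rises = {}
        for i, term in enumerate(current):
            terms = current[:i] + current[i + 1:]
            fit = _fit_terms(prep, theta, terms, dict(warm), **fit_kw)
            if not fit.converged:
                log.warning("backward step removing %s did not converge; "
                            "skipped", term.covariate)
                continue
            rises[i] = (fit, fit.ofv - cur_ofv)
        if not rises:
            break
        i_min = min(rises, key=lambda i: rises[i][1])
        fit, rise = rises[i_min]
        name = current[i_min].covariate
        if rise < backward_threshold:
            current = current[:i_min] + current[i_min + 1:]
            cur_ofv, cur_fit = fit.ofv, fit
            warm.update(fit.params)
            steps.append(SelectionStep("remove", name, _label(current),
                                       fit.ofv, rise))
        else:
            break
        if not current:
            break

    return SelectionTrace(steps, current, cur_fit)


def _label(terms: tuple) -> str:
    if not terms:
        return "Base model"
    return "Base model + " + " + ".join(
        f"{t.covariate.upper()} on EC50" for t in terms)


def bootstrap_validate(cohort, final_fit: FitResult,
                       n_boot: int = 200, seed: int = 0,
                       theta: Optional[ThetaVector] = None,
                       dt: float = 1.0, **fit_kw) -> BootstrapResult:
    """Nonparametric bootstrap of the final model.

    Subjects are resampled with replacement to the original cohort size and
    the estimated parameters refit (warm-started from the original estimates).
    A replicate counts as a minimization success when the optimizer converged
    to a finite OFV without hitting a parameter bound.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    theta = theta if theta is not None else final_fit.theta_hat
    prep = cohort if isinstance(cohort, PreparedCohort) \
        else PreparedCohort(cohort, theta, dt=dt)
    prep.warm_covariates(final_fit.terms)
    fit_kw.setdefault("compute_rse", False)
    fit_kw.setdefault("effort", "fast")

    estimate = list(final_fit.params)
    # fixed (non-estimated) omega/sigma must carry over from the original fit
    init = {"omega": final_fit.omega_hat, "sigma": final_fit.sigma_hat,
            **final_fit.params}
    rng = np.random.default_rng(seed)
    samples = {k: [] for k in estimate}
    n_success = 0
    failures = []
    for b in range(n_boot):
        idx = rng.integers(0, prep.n, size=prep.n)
        sub = prep.subset(idx)
        fit = fit_population(sub, theta, terms=final_fit.terms,
                             estimate=estimate, init=init, **fit_kw)
        ok = fit.converged and np.isfinite(fit.ofv) and not fit.boundary_hits
        if ok:
            n_success += 1
            for k in estimate:
                samples[k].append(fit.params[k])
        else:
            failures.append(b)
    if n_success == 0:
        raise RuntimeError(
            f"all {n_boot} bootstrap replicates failed "
            f"(non-convergence or bound hits in replicates {failures[:5]}...)")
    arr = {k: np.asarray(v) for k, v in samples.items()}
    return BootstrapResult(
        n_requested=n_boot, n_success=n_success,
        medians={k: float(np.median(v)) for k, v in arr.items()},
        q025={k: float(np.percentile(v, 2.5)) for k, v in arr.items()},
        q975={k: float(np.percentile(v, 97.5)) for k, v in arr.items()},
        original=dict(final_fit.params),
        samples=arr,
    )
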