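"""Vectorized cohort-level evaluation of the INR model likelihood.

The population objective needs the model prediction at every observation of
every subject, repeatedly, inside nested optimizations (MAP inner loop, outer
parameter search, bootstrap).  Because the PK side is fixed and the Hill
exponent is fixed, each subject's C(t)^gamma on a shared uniform time grid can
be precomputed once; a full-cohort INR evaluation then reduces to a broadcast
Hill transform plus four linear-filter passes and a gather, which is what
`PreparedCohort` implements.  The MAP inner problem (one scalar random effect
per subject) is solved for all subjects simultaneously by a coarse grid scan
followed by vectorized golden-section refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .model_core import (
    ThetaVector,
    PatientRecord,
    clearance_for,
    concentration_profile,
    covariate_value,
    transit_deficit,
    vkorc1_allele_weights,
    EC50_FLOOR,
)

__all__ = ["CovariateTerm", "final_model_terms", "PreparedCohort",
           "cohort_objectives", "map_etas", "laplace_components"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate effect on EC50.

    kind "power": multiplies TVEC50 by (x / center) ** coef  (continuous).
    kind "shift": adds x * coef in mg/L                      (binary flag).
    """

    kind: str
    covariate: str
    center: float = 1.0
    coef: float = 0.0

    def __post_init__(self):
        if self.kind not in ("power", "shift"):
            raise ValueError(f"unknown covariate term kind {self.kind!r}")
        if self.kind == "power" and self.center <= 0:
            raise ValueError("power term center must be positive")

    def with_coef(self, coef: float) -> "CovariateTerm":
        return replace(self, coef=float(coef))


def final_model_terms(theta: ThetaVector) -> tuple:
    """The published covariate model: weight power + amiodarone shift on EC50."""
    return (
        CovariateTerm("power", "weight", center=theta.wt_ref, coef=theta.theta_wt),
        CovariateTerm("shift", "cm1", coef=theta.theta_cm1),
    )


class PreparedCohort:
    """Per-cohort precomputations for fast repeated likelihood evaluation.

    Observations at TIME=0 are excluded from the likelihood: the generator and
    the dataset format carry the pre-treatment baseline as a TIME=0 INR row,
    which defines the BASE covariate rather than an independent measurement.
    """

    def __init__(self, patients: Sequence[PatientRecord],
                 theta: ThetaVector, dt: float = 1.0):
        self.patients = list(patients)
        self.theta = theta
        self.dt = float(dt)
        self.n = len(self.patients)
        if self.n == 0:
            raise ValueError("cohort is empty")

        obs_t, obs_y, subj_idx = [], [], []
        for i, p in enumerate(self.patients):
            for t, y in p.observations:
                if t > 0 and np.isfinite(y):
                    obs_t.append(t)
                    obs_y.append(y)
                    subj_idx.append(i)
        self.obs_t = np.asarray(obs_t, dtype=float)
        self.y = np.asarray(obs_y, dtype=float)
        self.subj_idx = np.asarray(subj_idx, dtype=np.intp)
        self.m = self.y.size
        self.n_obs = np.bincount(self.subj_idx, minlength=self.n)

        t_end = float(self.obs_t.max()) if self.m else self.dt
        self.grid = np.arange(0.0, t_end + self.dt, self.dt)
        nt = self.grid.size

        cg = np.empty((self.n, nt))
        for i, p in enumerate(self.patients):
            cl = clearance_for(p.cyp2c9, p.age, theta)
            c = concentration_profile(p.doses, cl, theta, self.grid)
            cg[i] = c ** theta.gamma
        self.cg = cg

        w = np.array([vkorc1_allele_weights(p.vkorc1) for p in self.patients])
        self.wg, self.wa = w[:, 0].copy(), w[:, 1].copy()
        self.base = np.array([p.inr_base for p in self.patients])
        self._cov_cache: dict = {}

        # linear-interpolation gather indices into the grid
        pos = self.obs_t / self.dt
        self.i0 = np.clip(np.floor(pos).astype(np.intp), 0, nt - 2)
        self.w1 = pos - self.i0

        # per-subject contiguous slices in the flat observation arrays
        order = np.argsort(self.subj_idx, kind="stable")
        assert np.array_equal(order, np.arange(self.m))  # built subject-major
        self.starts = np.concatenate([[0], np.cumsum(self.n_obs)])

    # -- covariates -------------------------------------------------------
    def covariate(self, name: str) -> np.ndarray:
        if name not in self._cov_cache:
            self._cov_cache[name] = np.array(
                [covariate_value(p, name) for p in self.patients])
        return self._cov_cache[name]

    def typical_ec50s(self, ec50_g: float, ec50_a: float,
                      terms: Sequence[CovariateTerm]) -> np.ndarray:
        tv = self.wg * ec50_g + self.wa * ec50_a
        shift = 0.0
        for term in terms:
            x = self.covariate(term.covariate)
            if term.kind == "power":
                tv = tv * (x / term.center) ** term.coef
            else:
                shift = shift + x * term.coef
        return np.maximum(tv + shift, EC50_FLOOR)

    # -- model evaluation -------------------------------------------------
    def predict_obs(self, ec50_ind: np.ndarray) -> np.ndarray:
        """Noiseless INR at each observation, given per-subject individual EC50."""
        th = self.theta
        den = ec50_ind ** th.gamma
        eff = th.emax * self.cg / (den[:, None] + self.cg)
        deficit = transit_deficit(eff, self.dt, th)
        inr = self.base[:, None] + th.inr_max * deficit
        f0 = inr[self.subj_idx, self.i0]
        f1 = inr[self.subj_idx, self.i0 + 1]
        return f0 * (1.0 - self.w1) + f1 * self.w1

    def subset(self, indices: Sequence[int]) -> "PreparedCohort":
        """Resampled/selected view (e.g. a bootstrap replicate); reuses the
        precomputed per-subject concentration grids."""
        idx = np.asarray(indices, dtype=np.intp)
        new = object.__new__(PreparedCohort)
        new.patients = [self.patients[i] for i in idx]
        new.theta = self.theta
        new.dt = self.dt
        new.n = idx.size
        new.grid = self.grid
        new.cg = self.cg[idx]
        new.wg, new.wa = self.wg[idx], self.wa[idx]
        new.base = self.base[idx]
        new._cov_cache = {k: v[idx] for k, v in self._cov_cache.items()}

        counts = self.n_obs[idx]
        sel = np.concatenate(
            [np.arange(self.starts[i], self.starts[i + 1]) for i in idx]
        ) if idx.size else np.empty(0, dtype=np.intp)
        new.obs_t = self.obs_t[sel]
        new.y = self.y[sel]
        new.i0 = self.i0[sel]
        new.w1 = self.w1[sel]
        new.m = new.y.size
        new.subj_idx = np.repeat(np.arange(idx.size, dtype=np.intp), counts)
        new.n_obs = counts
        new.starts = np.concatenate([[0], np.cumsum(counts)])
        return new

    # needed because _cov_cache is filled lazily after subsets may be taken
    def warm_covariates(self, terms: Sequence[CovariateTerm]) -> None:
        for term in terms:
            self.covariate(term.covariate)


def cohort_objectives(prep: PreparedCohort, ec50_g: float, ec50_a: float,
                      terms: Sequence[CovariateTerm], omega: float,
                      sigma: float, eta: np.ndarray) -> np.ndarray:
    """Per-subject -2 log(likelihood x prior), the MAP objective

        sum_obs [ (y-f)^2/(sigma f)^2 + ln(2 pi (sigma f)^2) ]
        + eta^2/omega^2 + ln(2 pi omega^2)
    """
    eta = np.asarray(eta, dtype=float)
    typ = prep.typical_ec50s(ec50_g, ec50_a, terms)
    f = prep.predict_obs(typ * np.exp(eta))
    sf2 = (sigma * f) ** 2
    terms_obs = (prep.y - f) ** 2 / sf2 + np.log(2.0 * np.pi * sf2)
    s = np.bincount(prep.subj_idx, weights=terms_obs, minlength=prep.n)
    return s + eta ** 2 / omega ** 2 + np.log(2.0 * np.pi * omega ** 2)


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def map_etas(prep: PreparedCohort, ec50_g: float, ec50_a: float,
             terms: Sequence[CovariateTerm], omega: float, sigma: float,
             span: float = 4.0, grid_pts: int = 9,
             iters: int = 18) -> np.ndarray:
    """Empirical-Bayes (MAP) eta for every subject simultaneously.

    Coarse scan over [-span*omega, span*omega] followed by golden-section
    refinement within each subject's bracketing interval; one full-cohort
    objective evaluation per refinement iteration.
    """

    def obj(e):
        return cohort_objectives(prep, ec50_g, ec50_a, terms, omega, sigma, e)

    # absolute floor on the search half-width so that trial values of omega
    # well below the data-generating scale cannot clamp outlying subjects
    half = max(span * omega, 2.5)
    grid = np.linspace(-half, half, grid_pts)
    vals = np.stack([obj(np.full(prep.n, g)) for g in grid])
    j = np.argmin(vals, axis=0)
    a = grid[np.maximum(j - 1, 0)]
    b = grid[np.minimum(j + 1, grid_pts - 1)]

    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1 = obj(x1)
    f2 = obj(x2)
    for _ in range(iters):
        m = f1 < f2
        b = np.where(m, x2, b)
        a = np.where(m, a, x1)
        x1_new = np.where(m, b - _INVPHI * (b - a), x2)
        x2_new = np.where(m, x1, a + _INVPHI * (b - a))
        x_eval = np.where(m, x1_new, x2_new)
        f_eval = obj(x_eval)
        f1, f2 = np.where(m, f_eval, f2), np.where(m, f1, f_eval)
        x1, x2 = x1_new, x2_new
    return 0.5 * (a + b)


def laplace_components(prep: PreparedCohort, ec50_g: float, ec50_a: float,
                       terms: Sequence[CovariateTerm], omega: float,
                       sigma: float, h_rel: float = 1e-3):
    """Per-subject Laplace-approximate -2 log marginal likelihood.

    For each subject:  obj(eta_hat) + ln(obj''(eta_hat)/2) - ln(2 pi),
    with the curvature from a central difference.  A subject with no
    observations contributes exactly 0 (the prior integrates to 1).  A
    non-positive curvature falls back to the prior curvature 2/omega^2.
    """
    if sigma < 0.1:
        # near-degenerate residual noise makes the inner objective extremely
        # steep; refine the mode further so OFV noise stays negligible
        eta_hat = map_etas(prep, ec50_g, ec50_a, terms, omega, sigma,
                           grid_pts=17, iters=50)
    else:
        eta_hat = map_etas(prep, ec50_g, ec50_a, terms, omega, sigma)

    def obj(e):
        return cohort_objectives(prep, ec50_g, ec50_a, terms, omega, sigma, e)

    h = h_rel * omega
    f0 = obj(eta_hat)
    hess = (obj(eta_hat + h) - 2.0 * f0 + obj(eta_hat - h)) / h ** 2
    bad = ~(hess > 0)
    if np.any(bad):
        hess = np.where(bad, 2.0 / omega ** 2, hess)
    ofv_i = f0 + np.log(hess / 2.0) - _LOG2PI
    return ofv_i, eta_hat, bad
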