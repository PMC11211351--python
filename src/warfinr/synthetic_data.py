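"""Virtual warfarin cohorts emulating the study population.

Covariate distributions follow the published cohort summary for the Han
anticoagulation study this model was estimated on: age 54.7 +/- 12.5 yr
(range 1-82), weight 59.7 +/- 11.6 kg (7-106), CYP2C9 *1/*1 94.3% / *1/*3
5.7%, VKORC1 AA 80.3% / GA 18.7% / GG 0.9%, amiodarone co-medication 25.7%,
baseline INR 1.13.  The sampling design mirrors the study: once-daily dosing
on the 0.625-6.25 mg grid, INR measured within 24 h post-dose and mostly
7-10 h after intake, roughly eight post-baseline measurements per subject.

Each subject's constant daily dose is chosen clinically plausibly but without
titration: the grid dose whose typical-patient (eta = 0) steady-state average
concentration hits a target INR, plus one random grid step of jitter.
Observed INR carries a proportional error, y = f * (1 + eps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model_core import (
    DEFAULT_THETA,
    PatientRecord,
    ThetaVector,
    clearance_for,
    individual_ec50,
    inr_trajectory,
    typical_ec50,
)

__all__ = ["CohortSpec", "SimulatedCohort", "sample_cohort",
           "simulate_observations", "split_cohort", "typical_grid_dose"]

log = logging.getLogger(__name__)

INR_CLIP = 0.3  # resample-once-then-clip floor for noisy INR observations


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a virtual cohort (defaults = study cohort)."""

    n_subjects: int = 200
    seed: int = 0
    age_mean: float = 54.7
    age_sd: float = 12.5
    age_bounds: tuple = (1.0, 82.0)
    weight_mean: float = 59.7
    weight_sd: float = 11.6
    weight_bounds: tuple = (7.0, 106.0)
    height_mean: float = 161.9
    height_sd: float = 9.3
    height_bounds: tuple = (80.0, 197.0)
    freq_cyp2c9: tuple = (("*1/*1", 0.943), ("*1/*3", 0.057))
    freq_vkorc1: tuple = (("AA", 0.803), ("GA", 0.187), ("GG", 0.009))
    p_amiodarone: float = 0.257
    p_female: float = 0.489
    p_cm2: float = 0.026  # azole antifungals
    p_cm3: float = 0.373  # statins
    p_cm4: float = 0.006  # broad-spectrum antibiotics
    inr_base_mean: float = 1.13
    inr_base_sd: float = 0.15
    inr_base_min: float = 0.82
    dose_grid: tuple = tuple(round(0.625 * k, 4) for k in range(1, 11))
    obs_per_subject: tuple = (7, 9)  # post-baseline INR measurements (inclusive)
    obs_window: tuple = (0.0, 24.0)  # h post-dose
    obs_mode_window: tuple = (7.0, 10.0)  # h post-dose, preferred draw window
    p_mode_window: float = 0.7
    horizon_days: int = 15
    target_inr: float = 2.2
    dose_jitter: bool = True

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("age_sd", "weight_sd", "height_sd", "inr_base_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.dose_grid:
            raise ValueError("dose_grid must be non-empty")
        for freqs in (self.freq_cyp2c9, self.freq_vkorc1):
            total = sum(p for _, p in freqs)
            if total <= 0:
                raise ValueError("genotype frequencies must sum to > 0")
        if self.obs_per_subject[0] < 1:
            raise ValueError("need at least one observation per subject")


@dataclass
class SimulatedCohort:
    """Cohort with simulated observations plus the generating ground truth."""

    patients: list
    true_etas: np.ndarray
    theta_true: ThetaVector
    omega_true: float
    sigma_true: float
    seed: int

    def truth_dict(self) -> dict:
        return {
            "theta": self.theta_true.to_dict(),
            "omega": self.omega_true,
            "sigma": self.sigma_true,
            "etas": {p.id: float(e)
                     for p, e in zip(self.patients, self.true_etas)},
            "seed": self.seed,
        }


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Truncated normal by rejection."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _categorical(rng, freqs, size):
    labels = [l for l, _ in freqs]
    p = np.array([w for _, w in freqs], dtype=float)
    p /= p.sum()
    cdf = np.cumsum(p)
    u = rng.random(size)
    idx = np.searchsorted(cdf, u, side="right")
    return [labels[i] for i in np.minimum(idx, len(labels) - 1)]


def typical_grid_dose(vkorc1: str, cyp2c9: str, age: float, weight: float,
                      cm1: int, inr_base: float,
                      theta: ThetaVector = DEFAULT_THETA,
                      target_inr: float = 2.2,
                      dose_grid: Sequence[float] = CohortSpec.dose_grid) -> float:
    """Grid dose whose typical-patient steady-state average concentration
    yields the target INR (closed form via Css,avg = D / (CL * 24)); clipped
    to the grid range."""
    e_star = (target_inr - inr_base) / theta.inr_max
    grid = np.asarray(dose_grid, dtype=float)
    if e_star >= theta.emax:
        return float(grid.max())
    if e_star <= 0:
        return float(grid.min())
    ec50 = typical_ec50(vkorc1, weight, cm1, theta)
    c_star = ec50 * (e_star / (theta.emax - e_star)) ** (1.0 / theta.gamma)
    cl = clearance_for(cyp2c9, age, theta)
    d = c_star * cl * 24.0
    return float(grid[np.argmin(np.abs(grid - d))])


def sample_cohort(spec: CohortSpec) -> list:
    """Draw covariates, dosing regimens and observation schedules.

    Returns PatientRecords with empty observations; the planned measurement
    times are carried in ``extras['obs_times']`` until `simulate_observations`
    fills in values.  Fully deterministic given ``spec`` (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    age = _trunc_normal(rng, spec.age_mean, spec.age_sd, *spec.age_bounds, size=n)
    weight = _trunc_normal(rng, spec.weight_mean, spec.weight_sd,
                           *spec.weight_bounds, size=n)
    height = _trunc_normal(rng, spec.height_mean, spec.height_sd,
                           *spec.height_bounds, size=n)
    cyp = _categorical(rng, spec.freq_cyp2c9, n)
    vk = _categorical(rng, spec.freq_vkorc1, n)
    cm1 = (rng.random(n) < spec.p_amiodarone).astype(int)
    sex = np.where(rng.random(n) < spec.p_female, 2, 1)  # 1 male, 2 female
    cm2 = (rng.random(n) < spec.p_cm2).astype(int)
    cm3 = (rng.random(n) < spec.p_cm3).astype(int)
    cm4 = (rng.random(n) < spec.p_cm4).astype(int)
    base = _trunc_normal(rng, spec.inr_base_mean, spec.inr_base_sd,
                         spec.inr_base_min, np.inf, size=n)

    grid = np.asarray(spec.dose_grid, dtype=float)
    patients = []
    for i in range(n):
        dose = typical_grid_dose(vk[i], cyp[i], age[i], weight[i], int(cm1[i]),
                                 base[i], target_inr=spec.target_inr,
                                 dose_grid=spec.dose_grid)
        if spec.dose_jitter:
            step = rng.choice([-1, 0, 0, 1]) * (grid[1] - grid[0]
                                                if grid.size > 1 else 0.0)
            dose = float(np.clip(dose + step, grid.min(), grid.max()))
        doses = [(24.0 * d, dose) for d in range(spec.horizon_days)]

        n_obs = int(rng.integers(spec.obs_per_subject[0],
                                 spec.obs_per_subject[1] + 1))
        days = rng.choice(np.arange(1, spec.horizon_days), size=n_obs,
                          replace=n_obs > spec.horizon_days - 1)
        use_mode = rng.random(n_obs) < spec.p_mode_window
        tod = np.where(use_mode,
                       rng.uniform(*spec.obs_mode_window, size=n_obs),
                       rng.uniform(*spec.obs_window, size=n_obs))
        times = np.sort(24.0 * (days - 1) + 24.0 + tod)  # h after first dose
        # i.e. measurements fall on dosing days 1..horizon-1, tod hours post-dose

        bmi = weight[i] / (height[i] / 100.0) ** 2
        patients.append(PatientRecord(
            id=f"S{i + 1:04d}", age=float(age[i]), weight=float(weight[i]),
            cyp2c9=cyp[i], vkorc1=vk[i], cm1=int(cm1[i]),
            inr_base=float(base[i]), doses=doses, observations=[],
            extras={
                "sex": int(sex[i]), "height_cm": float(height[i]),
                "bmi": float(bmi), "cm2": int(cm2[i]), "cm3": int(cm3[i]),
                "cm4": int(cm4[i]), "obs_times": times,
            },
        ))
    return patients


def simulate_observations(patients: Sequence[PatientRecord],
                          theta: ThetaVector = DEFAULT_THETA,
                          omega: float = 0.558, sigma: float = 0.365,
                          seed: int = 0, dt: float = 0.5) -> SimulatedCohort:
    """Simulate INR observations with lognormal IIV on EC50 and proportional
    residual error.

    Observation times come from each record's ``extras['obs_times']`` (falling
    back to existing observation times).  A noisy INR below 0.3 is redrawn
    once, then clipped; the pre-dose baseline row (TIME 0, INR = baseline) is
    always included.
    """
    if omega < 0 or sigma < 0:
        raise ValueError("omega and sigma must be non-negative")
    rng = np.random.default_rng(seed)
    etas = rng.normal(0.0, omega, size=len(patients)) if omega > 0 \
        else np.zeros(len(patients))

    out = []
    n_clipped = 0
    for p, eta in zip(patients, etas):
        times = np.asarray(p.extras.get("obs_times", p.obs_times), dtype=float)
        times = times[times > 0]
        f = inr_trajectory(p, float(eta), theta, times=times, dt=dt).inr
        eps = rng.normal(0.0, sigma, size=f.size) if sigma > 0 \
            else np.zeros(f.size)
        y = f * (1.0 + eps)
        low = y < INR_CLIP
        if np.any(low):
            eps2 = rng.normal(0.0, sigma, size=int(low.sum()))
            y[low] = f[low] * (1.0 + eps2)
            still = y < INR_CLIP
            if np.any(still):
                n_clipped += int(still.sum())
                y[still] = INR_CLIP
        obs = [(0.0, p.inr_base)] + list(zip(times.tolist(), y.tolist()))
        extras = dict(p.extras)
        extras.pop("obs_times", None)
        out.append(replace(p, observations=obs, extras=extras))
    if n_clipped:
        log.info("clipped %d observations at INR=%.1f", n_clipped, INR_CLIP)
    return SimulatedCohort(out, etas, theta, omega, sigma, seed)


def split_cohort(patients: Sequence[PatientRecord],
                 validation_fraction: float = 0.17):
    """ID-ordered modelling/validation split (the study used the first ~17%
    of subject IDs as the validation set)."""
    ordered = sorted(patients, key=lambda p: p.id)
    n_val = int(round(validation_fraction * len(ordered)))
    return ordered[n_val:], ordered[:n_val]
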