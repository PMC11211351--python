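"""Structural warfarin PK/PD (INR) model.

One-compartment oral PK with additive per-allele CYP2C9 clearance and a linear
age effect; sigmoid-Emax inhibition of clotting-factor synthesis driven by
warfarin concentration; two parallel transit-compartment chains whose combined
deficit maps linearly onto the INR scale:

    CL      = (CL_allele1 + CL_allele2) * (1 + age_slope * (AGE - age_ref))
    EC50    = TVEC50 * (WT/wt_ref)^theta_wt + CM1 * theta_cm1
    EFF(t)  = Emax * C(t)^gamma / (EC50_i^gamma + C(t)^gamma)
    dA_j1/dt = ktr_j * (1 - EFF) - ktr_j * A_j1,   ktr_j = n_j / MTT_j
    dA_jk/dt = ktr_j * (A_j,k-1 - A_jk)
    INR(t)  = INR_base + INR_max * (1 - (A_1,n1 + A_2,n2) / 2)

TVEC50 is the mean of the two VKORC1 allele EC50 values (so the homozygotes
equal the per-allele numbers); clearance is the sum of the two CYP2C9 allele
values (which reproduces the six-genotype clearance ordering).  A single
lognormal random effect acts on EC50.

The transit chains are linear and time-invariant in the forcing 1 - EFF(t), so
they are integrated by exact first-order-hold discretization of each stage
(`transit_deficit`) rather than a generic ODE solver; for constant forcing the
scheme is exact, and tests check it against `scipy.integrate.solve_ivp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap

__all__ = [
    "ThetaVector",
    "PatientRecord",
    "StateTrajectory",
    "DEFAULT_THETA",
    "CYP2C9_ALLELES",
    "VKORC1_GENOTYPES",
    "parse_diplotype",
    "vkorc1_allele_weights",
    "clearance_for",
    "typical_ec50",
    "individual_ec50",
    "concentration_profile",
    "inhibition",
    "transit_deficit",
    "inr_trajectory",
    "covariate_value",
]

EC50_FLOOR = 1e-6  # mg/L; positivity floor for covariate-adjusted EC50
CL_FLOOR = 1e-6  # L/h

CYP2C9_ALLELES = ("*1", "*2", "*3")
VKORC1_GENOTYPES = ("AA", "GA", "GG")


@dataclass(frozen=True)
class ThetaVector:
    """Population fixed effects of the warfarin INR model.

    Defaults are the final published estimates for the Han-population
    re-estimation of the reference (Hamberg-type) model: per-allele CYP2C9
    clearances and the age slope, apparent volume, Emax/gamma, per-VKORC1-allele
    EC50s with weight and amiodarone covariate coefficients, the two mean
    transit times and the INR scale factor.
    """

    cl_allele_1: float = 0.174  # L/h per *1 allele
    cl_allele_2: float = 0.0879  # L/h per *2 allele
    cl_allele_3: float = 0.0422  # L/h per *3 allele
    age_slope: float = -0.00571  # fractional CL change per year
    v_f: float = 14.3  # L, apparent volume of distribution
    ka: float = 2.0  # 1/h, first-order absorption rate (not reported; conventional)
    emax: float = 0.174  # maximal fractional inhibition
    gamma: float = 1.39  # Hill coefficient
    ec50_g: float = 4.3  # mg/L per VKORC1 G allele
    ec50_a: float = 1.14  # mg/L per VKORC1 A allele
    theta_wt: float = 1.34  # power of (WT/wt_ref) on EC50
    theta_cm1: float = -0.602  # mg/L additive EC50 shift when on amiodarone
    mtt1: float = 27.2  # h, mean transit time of chain 1
    mtt2: float = 110.9  # h, mean transit time of chain 2 (27.2 + 83.7)
    n1: int = 2  # transit compartments in chain 1
    n2: int = 2  # transit compartments in chain 2
    inr_max: float = 20.0  # INR units, maximal INR increment
    age_ref: float = 60.0  # yr, centering age for the CL age effect
    wt_ref: float = 60.0  # kg, centering weight in the EC50 covariate model

    def __post_init__(self) -> None:
        for name in ("cl_allele_1", "cl_allele_2", "cl_allele_3", "v_f", "ka",
                     "gamma", "ec50_g", "ec50_a", "mtt1", "mtt2", "inr_max",
                     "wt_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.emax <= 1:
            raise ValueError(f"emax must be in (0, 1], got {self.emax}")
        if self.mtt2 <= self.mtt1:
            raise ValueError("mtt2 must exceed mtt1")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("transit chain lengths must be >= 1")

    def with_updates(self, **kwargs) -> "ThetaVector":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThetaVector":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**known)


DEFAULT_THETA = ThetaVector()


@dataclass
class PatientRecord:
    """Covariates, dosing history and INR observations for one subject.

    ``doses`` and ``observations`` are sequences of (time_h, value) pairs;
    dose values are mg of racemic warfarin, observation values are INR.
    ``extras`` carries optional covariates used only for screening or
    comparator dose formulas (sex, height_cm, bmi, cm2..cm4, ...).
    """

    id: str
    age: float
    weight: float
    cyp2c9: str
    vkorc1: str
    cm1: int
    inr_base: float
    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        parse_diplotype(self.cyp2c9)
        if self.vkorc1 not in VKORC1_GENOTYPES:
            raise ValueError(f"unknown VKORC1 genotype {self.vkorc1!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.inr_base < 0.5:
            raise ValueError("inr_base must be >= 0.5")
        for t, amt in self.doses:
            if t < 0:
                raise ValueError("dose times must be non-negative")
            if not 0 < amt <= 20:
                raise ValueError(f"dose amount {amt} mg outside (0, 20]")
        if any(np.diff([t for t, _ in self.doses]) < 0):
            raise ValueError("dose times must be non-decreasing")
        if any(np.diff([t for t, _ in self.observations]) < 0):
            raise ValueError("observation times must be non-decreasing")

    @property
    def obs_times(self) -> np.ndarray:
        return np.asarray([t for t, _ in self.observations], dtype=float)

    @property
    def obs_values(self) -> np.ndarray:
        return np.asarray([v for _, v in self.observations], dtype=float)


@dataclass
class StateTrajectory:
    """Dense model state over time for one subject."""

    times: np.ndarray  # h
    concentration: np.ndarray  # mg/L
    eff: np.ndarray  # fractional inhibition
    chain1: np.ndarray  # (n1, nt) transit amounts, baseline 1
    chain2: np.ndarray  # (n2, nt)
    inr: np.ndarray  # INR units


def parse_diplotype(cyp2c9: str) -> tuple:
    """Split a CYP2C9 diplotype like ``"*1/*3"`` into its two alleles."""
    parts = str(cyp2c9).split("/")
    if len(parts) != 2:
        raise ValueError(f"cannot parse CYP2C9 diplotype {cyp2c9!r}")
    for allele in parts:
        if allele not in CYP2C9_ALLELES:
            raise ValueError(f"unknown CYP2C9 allele {allele!r}")
    return tuple(parts)


def _allele_cl(allele: str, theta: ThetaVector) -> float:
    return {"*1": theta.cl_allele_1,
            "*2": theta.cl_allele_2,
            "*3": theta.cl_allele_3}[allele]


def clearance_for(cyp2c9: str, age: float, theta: ThetaVector = DEFAULT_THETA) -> float:
    """Oral clearance (L/h): sum of the two allele contributions with a linear
    proportional age effect centered at ``theta.age_ref``."""
    if not 1 <= age <= 120:
        raise ValueError(f"age {age} outside [1, 120]")
    a1, a2 = parse_diplotype(cyp2c9)
    cl = (_allele_cl(a1, theta) + _allele_cl(a2, theta)) * (
        1.0 + theta.age_slope * (age - theta.age_ref))
    return max(cl, CL_FLOOR)


def vkorc1_allele_weights(vkorc1: str) -> tuple:
    """(weight on EC50_G, weight on EC50_A) so that TVEC50 is the allele mean."""
    try:
        return {"GG": (1.0, 0.0), "GA": (0.5, 0.5), "AA": (0.0, 1.0)}[vkorc1]
    except KeyError:
        raise ValueError(f"unknown VKORC1 genotype {vkorc1!r}") from None


def typical_ec50(vkorc1: str, weight: float, cm1: int,
                 theta: ThetaVector = DEFAULT_THETA) -> float:
    """Typical (pre-random-effect) EC50 in mg/L under the final covariate model

        EC50 = TVEC50 * (WT/wt_ref)^theta_wt + CM1 * theta_cm1

    with TVEC50 the mean of the two VKORC1 allele EC50 values.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    wg, wa = vkorc1_allele_weights(vkorc1)
    tv = wg * theta.ec50_g + wa * theta.ec50_a
    value = tv * (weight / theta.wt_ref) ** theta.theta_wt + cm1 * theta.theta_cm1
    return max(value, EC50_FLOOR)


def individual_ec50(typical: float, eta: float) -> float:
    """Individual EC50 under the lognormal random effect: typical * exp(eta)."""
    if typical <= 0:
        raise ValueError("typical EC50 must be positive")
    return typical * np.exp(eta)


def concentration_profile(doses: Sequence, cl: float,
                          theta: ThetaVector = DEFAULT_THETA,
                          times: np.ndarray = None) -> np.ndarray:
    """Warfarin concentration (mg/L) by exact superposition of one-compartment
    first-order-absorption dose responses.

    ``ke == ka`` is handled with the analytic limiting form D*ka*tau*exp(-ka*tau)/V.
    """
    if cl <= 0:
        raise ValueError("clearance must be positive")
    t = np.asarray(times, dtype=float)
    ke = cl / theta.v_f
    ka = theta.ka
    c = np.zeros_like(t)
    for td, amt in doses:
        tau = t - td
        mask = tau >= 0
        tau = np.where(mask, tau, 0.0)
        if abs(ka - ke) < 1e-12 * ka:
            term = amt * ka * tau * np.exp(-ka * tau) / theta.v_f
        else:
            term = (amt * ka / (theta.v_f * (ka - ke))
                    * (np.exp(-ke * tau) - np.exp(-ka * tau)))
        c += np.where(mask, term, 0.0)
    return c


def inhibition(c, ec50_i: float, theta: ThetaVector = DEFAULT_THETA):
    """Sigmoid-Emax fractional inhibition of clotting-factor synthesis."""
    if ec50_i <= 0:
        raise ValueError("ec50 must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cg = c ** theta.gamma
    return theta.emax * cg / (ec50_i ** theta.gamma + cg)


def _foh_stage(x: np.ndarray, k: float, dt: float,
               y0=1.0, x_pre=None) -> np.ndarray:
    """One first-order transit stage dy/dt = k*(x - y), advanced on a uniform
    grid by exact first-order-hold discretization (piecewise-linear input).

    Works on the last axis; ``y0`` is the state at the first sample and
    ``x_pre`` the (assumed constant) input before it.
    """
    a = np.exp(-k * dt)
    e = (1.0 - a) / (k * dt)
    b0 = 1.0 - e
    b1 = e - a
    if x_pre is None:
        x_pre = x[..., :1]
    zi = b1 * np.asarray(x_pre, dtype=float) + a * np.asarray(y0, dtype=float)
    zi = np.broadcast_to(zi, x.shape[:-1] + (1,)).copy()
    y, _ = lfilter([b0, b1], [1.0, -a], x, axis=-1, zi=zi)
    return y


def _foh_coefs(k: float, dt: float):
    a = np.exp(-k * dt)
    e = (1.0 - a) / (k * dt)
    return a, 1.0 - e, e - a


@_njit(cache=True)
def _transit22_kernel(u, a1, b01, b11, a2, b02, b12):
    """Both chains with two transit stages each, advanced jointly in one pass.

    Same first-order-hold recursion as `_foh_stage`, specialized to the
    default n1 = n2 = 2 configuration for speed inside the likelihood loops.
    """
    n, nt = u.shape
    out = np.empty((n, nt))
    for i in range(n):
        y11 = 1.0
        y12 = 1.0
        y21 = 1.0
        y22 = 1.0
        xprev = u[i, 0]
        for j in range(nt):
            x = u[i, j]
            y11n = a1 * y11 + b01 * x + b11 * xprev
            y12n = a1 * y12 + b01 * y11n + b11 * y11
            y21n = a2 * y21 + b02 * x + b12 * xprev
            y22n = a2 * y22 + b02 * y21n + b12 * y21
            out[i, j] = 1.0 - 0.5 * (y12n + y22n)
            xprev = x
            y11, y12, y21, y22 = y11n, y12n, y21n, y22n
    return out


def transit_deficit(eff: np.ndarray, dt: float,
                    theta: ThetaVector = DEFAULT_THETA,
                    return_chains: bool = False):
    """Combined transit-chain deficit 1 - (A_1,n1 + A_2,n2)/2 on a uniform grid.

    ``eff`` is EFF(t) sampled at spacing ``dt`` (last axis); all compartments
    start at their unperturbed steady state A = 1.
    """
    u = 1.0 - np.asarray(eff, dtype=float)
    if (_HAVE_NUMBA and not return_chains
            and theta.n1 == 2 and theta.n2 == 2):
        u2 = np.ascontiguousarray(np.atleast_2d(u))
        a1, b01, b11 = _foh_coefs(theta.n1 / theta.mtt1, dt)
        a2, b02, b12 = _foh_coefs(theta.n2 / theta.mtt2, dt)
        d = _transit22_kernel(u2, a1, b01, b11, a2, b02, b12)
        return d.reshape(np.shape(u)) if u.ndim != 2 else d
    chains = []
    outs = []
    for mtt, n in ((theta.mtt1, theta.n1), (theta.mtt2, theta.n2)):
        k = n / mtt
        stages = []
        x = u
        x_pre = u[..., :1]
        for _ in range(n):
            x = _foh_stage(x, k, dt, y0=1.0, x_pre=x_pre)
            stages.append(x)
            x_pre = 1.0  # downstream stages start from the unit steady state
        chains.append(stages)
        outs.append(x)
    deficit = 1.0 - 0.5 * (outs[0] + outs[1])
    if return_chains:
        return deficit, chains
    return deficit


def inr_trajectory(patient: PatientRecord, eta: float,
                   theta: ThetaVector = DEFAULT_THETA,
                   times: np.ndarray = None, dt: float = 0.5,
                   doses: Sequence = None) -> StateTrajectory:
    """Full INR trajectory for one subject at requested times.

    The model is evaluated on an internal uniform grid of spacing ``dt`` hours
    covering [0, max(times)] and linearly interpolated at ``times``.
    ``doses`` overrides the patient's recorded dosing history when given.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a sorted 1-D array")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if doses is None:
        doses = patient.doses
    t_end = float(times[-1]) if times.size else 0.0
    grid = np.arange(0.0, t_end + dt, dt)
    cl = clearance_for(patient.cyp2c9, patient.age, theta)
    conc = concentration_profile(doses, cl, theta, grid)
    ec50_i = individual_ec50(
        typical_ec50(patient.vkorc1, patient.weight, patient.cm1, theta), eta)
    eff = inhibition(conc, ec50_i, theta)
    deficit, chains = transit_deficit(eff, dt, theta, return_chains=True)
    inr = patient.inr_base + theta.inr_max * deficit

    def at(v):
        return np.interp(times, grid, v)

    return StateTrajectory(
        times=times,
        concentration=at(conc),
        eff=at(eff),
        chain1=np.vstack([at(s) for s in chains[0]]),
        chain2=np.vstack([at(s) for s in chains[1]]),
        inr=at(inr),
    )


def covariate_value(patient: PatientRecord, name: str) -> float:
    """Resolve a covariate by name from record fields or ``extras``.

    Raises ``KeyError`` naming the covariate when absent.
    """
    name = name.lower()
    direct = {
        "age": patient.age,
        "weight": patient.weight,
        "wt": patient.weight,
        "cm1": patient.cm1,
        "amiodarone": patient.cm1,
        "inr_base": patient.inr_base,
        "base": patient.inr_base,
    }
    if name in direct:
        return float(direct[name])
    if name in patient.extras:
        return float(patient.extras[name])
    raise KeyError(f"covariate {name!r} not available for subject {patient.id}")
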