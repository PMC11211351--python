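"""Dose individualization and comparison against regression dose models.

The mechanistic route inverts the PK/PD model: the maintenance dose is the
constant daily dose whose steady-state INR (average over one dosing interval
after >= 10 mean transit times of chain 2) hits the target, found by root
bracketing.  A-priori dosing uses eta = 0; a-posteriori dosing plugs in the
MAP eta from the subject's observed INRs.

Comparator dose models (IWPC, Gage, the FDA label genotype table) are simple
published regressions / lookups; their coefficients ship as editable YAML
configs marked with their external provenance.  Comparison metrics follow
common practice for warfarin dosing algorithms: MPE (mean absolute error,
mg/day), Pearson r, and the ideal / over / under prediction percentages with
"ideal" meaning within +/-20% of the actual stable dose (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import pearsonr

from .estimation import map_estimate
from .model_core import (
    DEFAULT_THETA,
    PatientRecord,
    ThetaVector,
    inr_trajectory,
    parse_diplotype,
)

__all__ = [
    "DosePrediction", "ComparatorSpec", "ComparisonReport", "TargetUnreachable",
    "predict_inr", "steady_state_inr", "find_maintenance_dose",
    "comparator_dose", "compare_models", "snap_to_grid",
]

DOSE_GRID_STEP = 0.625  # mg, the smallest divisible warfarin dose


class TargetUnreachable(ValueError):
    """Raised when no dose within bounds reaches the target INR.

    ``side`` is "high" when even the maximal dose falls short and "low" when
    the minimal dose already overshoots.
    """

    def __init__(self, message: str, side: str = "high"):
        super().__init__(message)
        self.side = side


@dataclass
class DosePrediction:
    model: str
    dose: float  # mg/day
    target_inr: Optional[float] = None
    eta: float = 0.0  # 0 = a-priori; MAP estimate = a-posteriori
    snapped: bool = False


@dataclass
class ComparatorSpec:
    """A published regression/lookup dose model.

    form: "linear" (mg), "sqrt" (linear predictor on sqrt(dose)),
    "log" (linear predictor on ln(dose)), or "table" (genotype lookup).
    scale: "daily" or "weekly" (weekly predictions are divided by 7).
    """

    name: str
    form: str
    scale: str = "daily"
    intercept: float = 0.0
    terms: tuple = ()  # (covariate_name, coefficient) pairs
    table: dict = field(default_factory=dict)  # cyp2c9 -> vkorc1 -> mg/day
    provenance: str = ""

    def __post_init__(self):
        if self.form not in ("linear", "sqrt", "log", "table"):
            raise ValueError(f"unknown comparator form {self.form!r}")
        if self.scale not in ("daily", "weekly"):
            raise ValueError(f"unknown dose scale {self.scale!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ComparatorSpec":
        return cls(
            name=d["name"], form=d["form"], scale=d.get("scale", "daily"),
            intercept=float(d.get("intercept", 0.0)),
            terms=tuple((t["covariate"], float(t["coef"]))
                        for t in d.get("terms", ())),
            table=d.get("table", {}), provenance=d.get("provenance", ""),
        )

    @classmethod
    def from_yaml(cls, path) -> "ComparatorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ComparisonReport:
    table: pd.DataFrame  # one row per model
    ideal_band: float

    def row(self, model: str) -> pd.Series:
        return self.table.set_index("model").loc[model]


def predict_inr(patient: PatientRecord, regimen: Sequence, eta: float = 0.0,
                theta: ThetaVector = DEFAULT_THETA,
                at_times: Sequence = (), dt: float = 0.5) -> np.ndarray:
    """Noiseless model INR under a dosing regimen at the requested times."""
    times = np.asarray(at_times, dtype=float)
    return inr_trajectory(patient, eta, theta, times=times, dt=dt,
                          doses=list(regimen)).inr


def steady_state_inr(patient: PatientRecord, daily_dose: float,
                     eta: float = 0.0, theta: ThetaVector = DEFAULT_THETA,
                     dt: float = 0.5) -> float:
    """Steady-state INR under constant daily dosing: the average INR over the
    final 24 h interval of a horizon of at least 10 x MTT2."""
    n_days = int(math.ceil(10.0 * theta.mtt2 / 24.0)) + 1
    regimen = [(24.0 * d, daily_dose) for d in range(n_days)]
    t_last = 24.0 * (n_days - 1)
    times = np.linspace(t_last, t_last + 24.0, 49)
    inr = predict_inr(patient, regimen, eta, theta, times, dt=dt)
    return float(np.trapezoid(inr, times) / 24.0)


def snap_to_grid(dose: float, step: float = DOSE_GRID_STEP) -> float:
    return round(max(round(dose / step), 1) * step, 4)


def find_maintenance_dose(patient: PatientRecord, target_inr: float,
                          eta: float = 0.0,
                          theta: ThetaVector = DEFAULT_THETA,
                          snap: bool = False,
                          dose_bounds: tuple = (1e-3, 20.0),
                          dt: float = 0.5) -> DosePrediction:
    """Maintenance dose reaching the target steady-state INR, by root
    bracketing over the (monotone) dose -> steady-state INR map."""
    if not patient.inr_base < target_inr < patient.inr_base + theta.inr_max:
        raise ValueError(
            f"target INR {target_inr} outside reachable range "
            f"({patient.inr_base}, {patient.inr_base + theta.inr_max})")
    lo, hi = dose_bounds

    def g(d):
        return steady_state_inr(patient, d, eta, theta, dt=dt) - target_inr

    g_lo, g_hi = g(lo), g(hi)
    if g_hi < 0:
        raise TargetUnreachable(
            f"target INR {target_inr} not reachable at {hi} mg/day "
            f"(steady-state INR {g_hi + target_inr:.3f})", side="high")
    if g_lo > 0:
        raise TargetUnreachable(
            f"steady-state INR already above target at {lo} mg/day",
            side="low")
    dose = float(brentq(g, lo, hi, xtol=1e-5, rtol=1e-10))
    if snap:
        dose = snap_to_grid(dose)
    return DosePrediction("pkpd", dose, target_inr=target_inr, eta=eta,
                          snapped=snap)


# ---------------------------------------------------------------------------
# comparator feature resolution

_CYP_LABELS = {"*1/*1": "11", "*1/*2": "12", "*1/*3": "13",
               "*2/*2": "22", "*2/*3": "23", "*3/*3": "33"}


def _feature(patient: PatientRecord, name: str) -> float:
    p = patient
    alleles = parse_diplotype(p.cyp2c9)
    derived = {
        "age": p.age,
        "age_decades": p.age / 10.0,
        "weight": p.weight,
        "cm1": float(p.cm1),
        "amiodarone": float(p.cm1),
        "vkorc1_ga": float(p.vkorc1 == "GA"),
        "vkorc1_aa": float(p.vkorc1 == "AA"),
        "vkorc1_gg": float(p.vkorc1 == "GG"),
        "vkorc1_a_count": float(p.vkorc1.count("A")),
        "cyp2c9_star2_count": float(alleles.count("*2")),
        "cyp2c9_star3_count": float(alleles.count("*3")),
    }
    for diplo, tag in _CYP_LABELS.items():
        derived[f"cyp2c9_{tag}"] = float(p.cyp2c9 == diplo)
    if name in derived:
        return derived[name]
    if name in ("height_cm", "bmi", "sex"):
        if name not in p.extras:
            raise KeyError(f"covariate {name!r} missing for subject {p.id}")
        return float(p.extras[name])
    if name == "sex_female":
        if "sex" not in p.extras:
            raise KeyError(f"covariate 'sex' missing for subject {p.id}")
        return float(p.extras["sex"] == 2)
    if name == "bsa":
        if "height_cm" not in p.extras:
            raise KeyError(f"covariate 'height_cm' missing for subject {p.id}")
        # DuBois & DuBois body surface area, m^2
        return 0.007184 * p.weight ** 0.425 * float(p.extras["height_cm"]) ** 0.725
    if name in p.extras:
        return float(p.extras[name])
    raise KeyError(f"covariate {name!r} missing for subject {p.id}")


def comparator_dose(spec: ComparatorSpec, patient: PatientRecord) -> DosePrediction:
    """Evaluate a regression/lookup dose model for one patient."""
    if spec.form == "table":
        try:
            dose = float(spec.table[patient.cyp2c9][patient.vkorc1])
        except KeyError as exc:
            raise KeyError(f"no table entry for ({patient.cyp2c9}, "
                           f"{patient.vkorc1}) in {spec.name}") from exc
    else:
        lp = spec.intercept + sum(coef * _feature(patient, name)
                                  for name, coef in spec.terms)
        if spec.form == "linear":
            dose = lp
        elif spec.form == "sqrt":
            dose = lp ** 2
        else:  # log
            dose = math.exp(lp)
    if spec.scale == "weekly":
        dose /= 7.0
    return DosePrediction(spec.name, max(float(dose), 0.0))


def _metrics(pred: np.ndarray, actual: np.ndarray, ideal_band: float) -> dict:
    err = pred - actual
    mpe = float(np.mean(np.abs(err)))
    rel = err / actual
    ideal = float(np.mean(np.abs(rel) <= ideal_band) * 100.0)
    over = float(np.mean(rel > ideal_band) * 100.0)
    under = float(np.mean(rel < -ideal_band) * 100.0)
    if pred.size >= 3 and np.std(pred) > 0 and np.std(actual) > 0:
        r = float(pearsonr(pred, actual)[0])
    else:
        r = float("nan")
    return {"mpe": mpe, "pearson_r": r, "ideal_pct": ideal,
            "over_pct": over, "under_pct": under}


def compare_models(patients: Sequence[PatientRecord],
                   actual_doses: Sequence[float],
                   specs: Sequence[ComparatorSpec] = (),
                   ppkpd: Optional[dict] = None,
                   ideal_band: float = 0.2) -> ComparisonReport:
    """Predict every subject's maintenance dose under each model and score
    against the actual doses.

    ``ppkpd`` enables the mechanistic predictor: a dict with optional keys
    theta (ThetaVector), target_inr (default 2.2), mode ("apriori" or "map"),
    omega/sigma (for MAP mode), snap (bool), name.
    """
    actual = np.asarray(actual_doses, dtype=float)
    if len(patients) != actual.size:
        raise ValueError("one actual dose per patient required")
    if np.any(actual <= 0):
        raise ValueError("actual doses must be positive")

    rows = []
    for spec in specs:
        pred = np.array([comparator_dose(spec, p).dose for p in patients])
        rows.append({"model": spec.name, **_metrics(pred, actual, ideal_band)})

    if ppkpd is not None:
        theta = ppkpd.get("theta", DEFAULT_THETA)
        target = ppkpd.get("target_inr", 2.2)
        mode = ppkpd.get("mode", "apriori")
        snap = ppkpd.get("snap", False)
        name = ppkpd.get("name", f"pkpd-{mode}")
        pred = np.empty(len(patients))
        for i, p in enumerate(patients):
            if mode == "map":
                eta = map_estimate(p, theta, ppkpd.get("omega", 0.558),
                                   ppkpd.get("sigma", 0.365)).eta_hat
            else:
                eta = 0.0
            try:
                pred[i] = find_maintenance_dose(p, target, eta, theta,
                                                snap=snap).dose
            except TargetUnreachable as exc:
                pred[i] = 20.0 if exc.side == "high" else DOSE_GRID_STEP
        rows.append({"model": name, **_metrics(pred, actual, ideal_band)})

    return ComparisonReport(pd.DataFrame(rows), ideal_band)
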