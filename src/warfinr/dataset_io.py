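"""NONMEM-style rectangular dataset and config I/O.

Columns: ID, TIME (h from first dose), EVID (1 dose / 0 observation), AMT
(mg, dose rows only), DV (INR, observation rows only), MDV, then the
covariates AGE, WT, SEX, BMI, CYP2C9, VKORC1, CM1..CM4 (amiodarone, azoles,
statins, broad-spectrum antibiotics) and BASE (pre-treatment INR).  Genotypes
are written as canonical text ("*1/*3", "GA"); NONMEM-style integer codes are
accepted on read via a documented alias map.  Floats are rendered with six
significant digits so repeated writes are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model_core import PatientRecord, ThetaVector

__all__ = [
    "COLUMNS", "CYP2C9_CODES", "VKORC1_CODES", "DatasetValidationError",
    "write_dataset", "read_dataset", "write_truth", "read_truth",
    "load_model_config", "save_model_config", "default_model_config_path",
    "comparator_dir",
]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DV", "MDV", "AGE", "WT", "SEX",
           "BMI", "CYP2C9", "VKORC1", "CM1", "CM2", "CM3", "CM4", "BASE"]

# NONMEM-style integer aliases for the genotype columns
CYP2C9_CODES = {"1": "*1/*1", "2": "*1/*2", "3": "*1/*3",
                "4": "*2/*2", "5": "*2/*3", "6": "*3/*3"}
VKORC1_CODES = {"1": "GG", "2": "GA", "3": "AA"}


class DatasetValidationError(ValueError):
    """Row-addressed dataset violations, collected and reported together."""

    def __init__(self, errors: Sequence[tuple]):
        self.errors = list(errors)
        msg = "; ".join(f"row {r}: {m}" for r, m in self.errors[:20])
        if len(self.errors) > 20:
            msg += f"; ... ({len(self.errors)} total)"
        super().__init__(f"invalid dataset: {msg}")


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


def write_dataset(records: Sequence[PatientRecord], path) -> None:
    """Write records as a NONMEM-style CSV (deterministic, byte-stable)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(COLUMNS)
        for p in records:
            rows = []
            for t, y in p.observations:
                rows.append((float(t), 0, 0, None, y))
            for t, amt in p.doses:
                rows.append((float(t), 1, 1, amt, None))
            # time-ordered; observations precede doses at equal times
            rows.sort(key=lambda r: (r[0], r[1]))
            x = p.extras

            def opt(key):
                return _fmt(x[key]) if key in x else ""

            cov = [_fmt(p.age), _fmt(p.weight), opt("sex"), opt("bmi"),
                   p.cyp2c9, p.vkorc1, str(p.cm1),
                   opt("cm2"), opt("cm3"), opt("cm4"),
                   _fmt(p.inr_base)]
            for t, evid, _, amt, dv in rows:
                mdv = 1 if evid == 1 or dv is None or not np.isfinite(dv) else 0
                w.writerow([p.id, _fmt(t), evid, _fmt(amt), _fmt(dv), mdv]
                           + cov)


def _decode_genotype(raw: str, codes: dict, valid: set, row: int,
                     errors: list, what: str):
    s = str(raw).strip()
    if s in valid:
        return s
    if s in codes:
        return codes[s]
    # tolerate float-ish integer codes like "1.0"
    try:
        key = str(int(float(s)))
        if key in codes:
            return codes[key]
    except ValueError:
        pass
    errors.append((row, f"unknown {what} code {raw!r}"))
    return None


def read_dataset(path) -> list:
    """Parse and validate a dataset CSV into PatientRecords.

    All row-level violations are collected and raised together as a
    `DatasetValidationError` with row numbers (1-based, header = row 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError([(1, f"missing column(s) {missing}")])

    errors: list = []

    def num(row_i, col, required=True):
        raw = df.at[row_i, col].strip()
        if raw == "":
            if required:
                errors.append((row_i + 2, f"missing {col}"))
            return None
        try:
            return float(raw)
        except ValueError:
            errors.append((row_i + 2, f"non-numeric {col} {raw!r}"))
            return None

    records = []
    for pid, grp in df.groupby("ID", sort=False):
        doses, obs = [], []
        covs = None
        last_t = {0: -np.inf, 1: -np.inf}
        for i in grp.index:
            row_no = i + 2
            t = num(i, "TIME")
            evid_f = num(i, "EVID")
            if t is None or evid_f is None:
                continue
            evid = int(evid_f)
            if evid not in (0, 1):
                errors.append((row_no, f"EVID must be 0 or 1, got {evid}"))
                continue
            amt_raw = df.at[i, "AMT"].strip()
            dv_raw = df.at[i, "DV"].strip()
            if t < 0:
                errors.append((row_no, f"negative TIME {t}"))
            if t < last_t[evid]:
                errors.append((row_no, f"non-monotone TIME within ID {pid}"))
            last_t[evid] = t
            if evid == 1:
                if dv_raw != "":
                    errors.append((row_no, "dose row (EVID=1) carries DV"))
                amt = num(i, "AMT")
                if amt is not None:
                    if amt <= 0:
                        errors.append((row_no, f"non-positive AMT {amt}"))
                    else:
                        doses.append((t, amt))
            else:
                if amt_raw != "":
                    errors.append((row_no, "observation row (EVID=0) carries AMT"))
                dv = num(i, "DV", required=False)
                obs.append((t, dv if dv is not None else np.nan))
            if covs is None:
                cyp = _decode_genotype(df.at[i, "CYP2C9"], CYP2C9_CODES,
                                       set(CYP2C9_CODES.values()), row_no,
                                       errors, "CYP2C9")
                vk = _decode_genotype(df.at[i, "VKORC1"], VKORC1_CODES,
                                      set(VKORC1_CODES.values()), row_no,
                                      errors, "VKORC1")
                age = num(i, "AGE")
                wt = num(i, "WT")
                cm1 = num(i, "CM1")
                base = num(i, "BASE", required=False)
                extras = {}
                for col, key in (("SEX", "sex"), ("BMI", "bmi"),
                                 ("CM2", "cm2"), ("CM3", "cm3"),
                                 ("CM4", "cm4")):
                    v = num(i, col, required=False)
                    if v is not None:
                        extras[key] = int(v) if col != "BMI" else v
                covs = (cyp, vk, age, wt, cm1, base, extras, row_no)
        if covs is None:
            errors.append((1, f"subject {pid} has no usable rows"))
            continue
        cyp, vk, age, wt, cm1, base, extras, first_row = covs
        if base is None:
            baseline = [y for t, y in obs if t == 0 and np.isfinite(y)]
            if baseline:
                base = baseline[0]
            else:
                errors.append((first_row,
                               f"subject {pid}: no BASE and no TIME=0 INR row"))
        if None in (cyp, vk, age, wt, cm1) or base is None:
            continue
        try:
            records.append(PatientRecord(
                id=str(pid), age=age, weight=wt, cyp2c9=cyp, vkorc1=vk,
                cm1=int(cm1), inr_base=base, doses=doses, observations=obs,
                extras=extras))
        except ValueError as exc:
            errors.append((first_row, f"subject {pid}: {exc}"))
    if errors:
        raise DatasetValidationError(sorted(errors))
    return records


# ---------------------------------------------------------------------------
# configs and ground truth

def write_truth(cohort, path) -> None:
    """Ground-truth sidecar (theta/omega/sigma/etas/seed) for a simulated
    cohort, as JSON."""
    with open(path, "w") as fh:
        json.dump(cohort.truth_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    d["theta"] = ThetaVector.from_dict(d["theta"])
    return d


def _data_dir() -> Path:
    return Path(__file__).parent / "data"


def default_model_config_path() -> Path:
    return _data_dir() / "model_default.yaml"


def comparator_dir() -> Path:
    return _data_dir() / "comparators"


def load_model_config(path=None):
    """Load a model config YAML: returns (ThetaVector, omega, sigma)."""
    path = Path(path) if path is not None else default_model_config_path()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    theta = ThetaVector.from_dict(cfg["theta"])
    return theta, float(cfg.get("omega", 0.558)), float(cfg.get("sigma", 0.365))


def save_model_config(theta: ThetaVector, omega: float, sigma: float, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"theta": theta.to_dict(), "omega": float(omega),
                        "sigma": float(sigma)}, fh, sort_keys=True)
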