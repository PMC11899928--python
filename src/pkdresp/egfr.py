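"""Kidney-function trajectory: CKD-EPI 2021 eGFR and group decline slopes.

eGFR is computed from serum creatinine with the race-free 2021 CKD-EPI
creatinine equation.  Per-patient change from the value at treatment start
(delta-eGFR) is regressed on time; responder and non-responder decline slopes
are compared through a pooled model with a group-by-time interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import PKDRespError, ValidationError

# CKD-EPI 2021 creatinine (race-free) constants
_KAPPA = {"F": 0.7, "M": 0.9}
_ALPHA = {"F": -0.241, "M": -0.302}
_FEMALE_FACTOR = 1.012
_AGE_BASE = 0.9938
_SCALE = 142.0
_MAX_EXP = -1.200


@dataclass
class EGFRPoint:
    patient_id: str
    months_since_start: float
    egfr: float
    delta_egfr: float | None = None  # egfr minus the patient's value at start


@dataclass(frozen=True)
class GroupSlope:
    slope: float       # mL/min/1.73 m^2 per year
    se: float
    ci: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class SlopeComparison:
    slopes: dict            # group -> GroupSlope
    interaction_p: float
    excess_percent: float   # how much faster the faster-declining group falls


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().upper()[:1]
    if s not in ("M", "F"):
        raise ValidationError(f"sex must be 'M' or 'F', got {sex!r}")
    return s


def ckd_epi_2021(creatinine_mg_dl, age_years, sex):
    """Race-free 2021 CKD-EPI eGFR (mL/min/1.73 m^2).

    142 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.200 * 0.9938^age * 1.012 [female],
    with k = 0.7 (F) / 0.9 (M) and alpha = -0.241 (F) / -0.302 (M).
    Accepts scalars or numpy arrays for creatinine and age (single sex).
    """
    scr = np.asarray(creatinine_mg_dl, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(scr <= 0):
        raise ValidationError(f"creatinine_mg_dl must be > 0, got {creatinine_mg_dl}")
    if np.any(age <= 0):
        raise ValidationError(f"age_years must be > 0, got {age_years}")
    s = _norm_sex(sex)
    ratio = scr / _KAPPA[s]
    egfr = (_SCALE
            * np.minimum(ratio, 1.0) ** _ALPHA[s]
            * np.maximum(ratio, 1.0) ** _MAX_EXP
            * _AGE_BASE ** age)
    if s == "F":
        egfr = egfr * _FEMALE_FACTOR
    return float(egfr) if egfr.ndim == 0 else egfr


def inverse_ckd_epi_2021(egfr, age_years, sex):
    """Serum creatinine (mg/dL) that yields ``egfr`` under CKD-EPI 2021.

    The equation is a strictly decreasing piecewise power law in creatinine,
    so the inverse is exact: the branch is chosen by comparing the target to
    the eGFR at the sex-specific knot Scr = kappa.
    """
    e = np.asarray(egfr, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(e <= 0):
        raise ValidationError(f"egfr must be > 0, got {egfr}")
    if np.any(age <= 0):
        raise ValidationError(f"age_years must be > 0, got {age_years}")
    s = _norm_sex(sex)
    base = _SCALE * _AGE_BASE ** age * (_FEMALE_FACTOR if s == "F" else 1.0)
    ratio = np.where(e >= base,
                     (e / base) ** (1.0 / _ALPHA[s]),   # Scr <= kappa branch
                     (e / base) ** (1.0 / _MAX_EXP))    # Scr > kappa branch
    scr = _KAPPA[s] * ratio
    return float(scr) if scr.ndim == 0 else scr


def delta_egfr_series(points: Sequence[EGFRPoint]) -> list[EGFRPoint]:
    """Fill ``delta_egfr`` for one patient's series, relative to the value at
    treatment start (the month-0 point if present, else the earliest point)."""
    if not points:
        raise PKDRespError("empty eGFR series")
    pts = sorted(points, key=lambda p: p.months_since_start)
    baseline = next((p for p in pts if p.months_since_start == 0), pts[0])
    return [EGFRPoint(patient_id=p.patient_id,
                      months_since_start=p.months_since_start,
                      egfr=p.egfr,
                      delta_egfr=p.egfr - baseline.egfr)
            for p in pts]


def add_delta_column(labs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-patient delta-eGFR on a labs table with columns
    (patient_id, months_since_start, egfr).  Patients lacking a month-0 row
    are referenced to their earliest visit."""
    labs = labs.sort_values(["patient_id", "months_since_start"]).copy()
    base = labs.groupby("patient_id")["egfr"].transform("first")
    labs["delta_egfr"] = labs["egfr"] - base
    return labs


def fit_group_slopes(labs: pd.DataFrame, labels: pd.Series,
                     horizon_months: float = 48.0) -> SlopeComparison:
    """Compare eGFR decline slopes between responder groups.

    Per-group slopes come from separate OLS fits of delta-eGFR on years since
    treatment start; the difference is tested by the group-by-time interaction
    of a pooled OLS model on the same points.  Slopes are per year.
    """
    df = labs[labs["months_since_start"] <= horizon_months].copy()
    if "delta_egfr" not in df.columns:
        df = add_delta_column(df)
    df["group"] = df["patient_id"].map(labels)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "patient_id"].unique()
        raise PKDRespError(f"patients without a group label: {list(missing)[:5]}")
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise PKDRespError(f"need two groups, found {groups}")
    df["years"] = df["months_since_start"] / 12.0

    slopes: dict[str, GroupSlope] = {}
    for g in groups:
        sub = df[df["group"] == g]
        if sub["years"].nunique() < 2:
            raise PKDRespError(f"group {g!r} has <2 distinct timepoints")
        X = sm.add_constant(sub["years"].to_numpy())
        fit = sm.OLS(sub["delta_egfr"].to_numpy(), X).fit()
        ci = fit.conf_int()[1]
        slopes[g] = GroupSlope(slope=float(fit.params[1]),
                               se=float(fit.bse[1]),
                               ci=(float(ci[0]), float(ci[1])),
                               n_points=int(len(sub)))

    # pooled model: delta ~ years * group (second group as the indicator)
    ind = (df["group"] == groups[1]).to_numpy(float)
    yrs = df["years"].to_numpy()
    X = np.column_stack([np.ones(len(df)), yrs, ind, yrs * ind])
    pooled = sm.OLS(df["delta_egfr"].to_numpy(), X).fit()
    interaction_p = float(pooled.pvalues[3])

    a, b = (slopes[g].slope for g in groups)
    slow, fast = sorted((abs(a), abs(b)))
    excess = float("nan") if slow == 0 else (fast - slow) / slow * 100.0
    return SlopeComparison(slopes=slopes, interaction_p=interaction_p,
                           excess_percent=excess)


def slope_excess_percent(slope_responder: float, slope_nonresponder: float) -> float:
    """Percent by which the non-responder decline exceeds the responder decline,
    on absolute slopes: (|s_nr| - |s_r|) / |s_r| * 100."""
    if slope_responder == 0:
        raise ValidationError("responder slope is zero; excess percent undefined")
    return (abs(slope_nonresponder) - abs(slope_responder)) / abs(slope_responder) * 100.0
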