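"""Per-patient exponential TKV growth-rate estimation.

Serial MRI visits yield several TKV measurements per scan (one per pulse
sequence covering both kidneys).  Each scan is collapsed to the mean TKV over
qualifying sequences; the log of that mean is regressed on age separately
before and during treatment (two-parameter least squares), and the fitted
slope ``b`` is reported as a compound annual growth rate ``(e^b - 1) * 100``
in percent per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EligibilityError, InsufficientDataError, MissingDataError

PRE = "pre"
DURING = "during"

# eligibility reason codes
TOO_FEW_PRE_SCANS = "TOO_FEW_PRE_SCANS"
PRE_SPAN_LT_1Y = "PRE_SPAN_LT_1Y"
TOO_FEW_DURING_SCANS = "TOO_FEW_DURING_SCANS"
DURING_SPAN_LT_1Y = "DURING_SPAN_LT_1Y"
TREATMENT_INTERRUPTION = "TREATMENT_INTERRUPTION_GT_1M"
NON_ADHERENCE = "NON_ADHERENCE"
CYST_EVENT = "CYST_EVENT"


@dataclass(frozen=True)
class SequenceMeasurement:
    sequence_id: str
    tkv_ml: float
    covers_both_kidneys: bool = True


@dataclass
class ScanRecord:
    """One MRI visit: all per-sequence TKV measurements at a given age."""

    patient_id: str
    age_at_scan: float
    measurements: list[SequenceMeasurement]

    def __post_init__(self):
        if self.age_at_scan <= 0:
            raise ValueError(f"age_at_scan must be > 0, got {self.age_at_scan}")
        if not self.measurements:
            raise ValueError("ScanRecord requires at least one measurement")
        for m in self.measurements:
            if m.tkv_ml <= 0:
                raise ValueError(f"tkv_ml must be > 0, got {m.tkv_ml}")


@dataclass(frozen=True)
class TKVPoint:
    age_at_scan: float
    mean_tkv: float
    n_sequences: int


@dataclass(frozen=True)
class GrowthFit:
    """Result of one exponential fit: log TKV = a + b * age on one window."""

    annual_rate: float        # (e^b - 1) * 100, percent per year
    tkv_at_ref_age: float     # fitted TKV (mL) at ref_age
    ref_age: float            # mean scan age of the window
    n_points: int
    log_residual_rms: float
    window: str               # "pre" | "during"


@dataclass(frozen=True)
class PatientFlags:
    """Chart-review exclusion flags; supplied as inputs, never inferred."""

    interruption_gt_1_month: bool = False
    non_adherence: bool = False
    cyst_event: bool = False


@dataclass(frozen=True)
class EligibilityDecision:
    patient_id: str
    eligible: bool
    reasons: tuple[str, ...] = field(default=())


def mean_tkv_per_scan(scan: ScanRecord) -> TKVPoint:
    """Arithmetic mean TKV over sequences imaging both kidneys in their entirety.

    Sequences that truncate a kidney are excluded; if none qualify the scan is
    unusable and :class:`MissingDataError` is raised.
    """
    vals = [m.tkv_ml for m in scan.measurements if m.covers_both_kidneys]
    if not vals:
        raise MissingDataError(
            f"scan of {scan.patient_id} at age {scan.age_at_scan:.2f}: "
            "no sequence covers both kidneys")
    return TKVPoint(age_at_scan=scan.age_at_scan,
                    mean_tkv=float(np.mean(vals)),
                    n_sequences=len(vals))


def fit_exponential_growth(points: Sequence[TKVPoint], window: str = PRE) -> GrowthFit:
    """OLS of ln(mean TKV) on age; slope annualized as a compound percent rate."""
    if len(points) < 2:
        raise InsufficientDataError(f"need >= 2 TKV points, got {len(points)}")
    ages = np.asarray([p.age_at_scan for p in points], dtype=float)
    if np.ptp(ages) == 0.0:
        raise InsufficientDataError("all scan ages identical; slope undefined")
    logs = np.log([p.mean_tkv for p in points])
    # centre ages for numerical stability; slope unchanged
    ref = float(ages.mean())
    slope, intercept = np.polyfit(ages - ref, logs, 1)
    resid = logs - (intercept + slope * (ages - ref))
    return GrowthFit(
        annual_rate=float((np.exp(slope) - 1.0) * 100.0),
        tkv_at_ref_age=float(np.exp(intercept)),
        ref_age=ref,
        n_points=len(points),
        log_residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        window=window,
    )


def split_pre_during(scans: Sequence[ScanRecord],
                     treatment_start_age: float) -> tuple[GrowthFit, GrowthFit]:
    """Fit the pre- and during-treatment windows independently.

    A scan falling exactly at the treatment start age belongs to the
    pre-treatment window (the drug cannot yet have acted at initiation).
    """
    pre_pts = [mean_tkv_per_scan(s) for s in scans if s.age_at_scan <= treatment_start_age]
    dur_pts = [mean_tkv_per_scan(s) for s in scans if s.age_at_scan > treatment_start_age]
    if len(pre_pts) < 2:
        raise EligibilityError(
            f"pre-treatment window has {len(pre_pts)} scan(s); >= 2 required")
    if len(dur_pts) < 2:
        raise EligibilityError(
            f"during-treatment window has {len(dur_pts)} scan(s); >= 2 required")
    return (fit_exponential_growth(pre_pts, window=PRE),
            fit_exponential_growth(dur_pts, window=DURING))


def apply_eligibility_filters(
    patients: Mapping[str, tuple[Sequence[ScanRecord], float, PatientFlags]],
) -> list[EligibilityDecision]:
    """Study inclusion/exclusion screen.

    Requires >=2 scans spanning >=1 year on each side of treatment start, no
    treatment interruption longer than one month, adherence, and no
    growth-perturbing cyst event (rupture/aspiration).  One reason code per
    violated criterion; a patient is eligible iff no reasons accrue.
    """
    decisions = []
    for pid, (scans, start_age, flags) in patients.items():
        reasons: list[str] = []
        pre_ages = sorted(s.age_at_scan for s in scans if s.age_at_scan <= start_age)
        dur_ages = sorted(s.age_at_scan for s in scans if s.age_at_scan > start_age)
        if len(pre_ages) < 2:
            reasons.append(TOO_FEW_PRE_SCANS)
        elif pre_ages[-1] - pre_ages[0] < 1.0:
            reasons.append(PRE_SPAN_LT_1Y)
        if len(dur_ages) < 2:
            reasons.append(TOO_FEW_DURING_SCANS)
        elif dur_ages[-1] - dur_ages[0] < 1.0:
            reasons.append(DURING_SPAN_LT_1Y)
        if flags.interruption_gt_1_month:
            reasons.append(TREATMENT_INTERRUPTION)
        if flags.non_adherence:
            reasons.append(NON_ADHERENCE)
        if flags.cyst_event:
            reasons.append(CYST_EVENT)
        decisions.append(EligibilityDecision(patient_id=pid,
                                             eligible=not reasons,
                                             reasons=tuple(reasons)))
    return decisions


# ---------------------------------------------------------------------------
# table-level helpers used by the pipeline


def scans_frame_to_records(scans_df: pd.DataFrame) -> dict[str, list[ScanRecord]]:
    """Group a scans table (patient_id, age_years, sequence_id, tkv_ml
    [, covers_both_kidneys]) into ScanRecord lists keyed by patient."""
    out: dict[str, list[ScanRecord]] = {}
    has_flag = "covers_both_kidneys" in scans_df.columns
    for (pid, age), grp in scans_df.groupby(["patient_id", "age_years"], sort=True):
        meas = [
            SequenceMeasurement(
                sequence_id=str(r.sequence_id),
                tkv_ml=float(r.tkv_ml),
                covers_both_kidneys=bool(r.covers_both_kidneys) if has_flag else True,
            )
            for r in grp.itertuples()
        ]
        out.setdefault(str(pid), []).append(
            ScanRecord(patient_id=str(pid), age_at_scan=float(age), measurements=meas))
    for pid in out:
        out[pid].sort(key=lambda s: s.age_at_scan)
    return out


def fit_cohort_growth(scans_df: pd.DataFrame,
                      patients_df: pd.DataFrame) -> pd.DataFrame:
    """Fit both windows for every patient; returns the growth_fits table."""
    records = scans_frame_to_records(scans_df)
    starts = patients_df.set_index("patient_id")["treatment_start_age"]
    rows = []
    for pid, scans in records.items():
        pre, dur = split_pre_during(scans, float(starts.loc[pid]))
        for fit in (pre, dur):
            rows.append({"patient_id": pid, "window": fit.window,
                         "annual_rate": fit.annual_rate,
                         "tkv_at_ref_age": fit.tkv_at_ref_age,
                         "ref_age": fit.ref_age,
                         "n_points": fit.n_points,
                         "log_residual_rms": fit.log_residual_rms})
    return pd.DataFrame(rows)
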