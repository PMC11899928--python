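"""Height-adjusted TKV and the Mayo Imaging Classification (classes 1A-1E).

The classification assigns each patient a theoretical annual kidney growth
rate from height-adjusted TKV (htTKV, mL/m) and age, assuming exponential
growth from a 150 mL/m reference kidney at birth:

    rate = ((htTKV / 150) ** (1 / age) - 1) * 100   [% per year]

Classes cut this rate at 1.5, 3, 4.5 and 6 %/yr.  The 150 mL/m reference and
the thresholds come from the classification's source publication, not derived
here; intervals are left-closed/right-open ([1.5, 3) -> 1B, etc.), a fixed
convention since the source states the thresholds only as ranges.  Patients
with htTKV below 150 mL/m get a nonpositive rate and fall in class 1A (not an
error).  Atypical/asymmetric disease (class 2) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

REFERENCE_HTTKV = 150.0                  # mL/m
CLASS_THRESHOLDS = (1.5, 3.0, 4.5, 6.0)  # %/yr
CLASS_NAMES = ("1A", "1B", "1C", "1D", "1E")


@dataclass(frozen=True)
class MICRecord:
    patient_id: str
    httkv: float             # mL/m
    age: float               # years
    theoretical_rate: float  # %/yr
    mic_class: str           # 1A..1E


def height_adjusted_tkv(tkv_ml: float, height_m: float) -> float:
    """htTKV = TKV / height (mL/m)."""
    if height_m <= 0:
        raise ValidationError(f"height_m must be > 0, got {height_m}")
    if tkv_ml <= 0:
        raise ValidationError(f"tkv_ml must be > 0, got {tkv_ml}")
    return tkv_ml / height_m


def theoretical_growth_rate(httkv: float, age: float) -> float:
    """Annual growth rate implied by reaching ``httkv`` at ``age`` from 150 mL/m."""
    if age <= 0:
        raise ValidationError(f"age must be > 0, got {age}")
    if httkv <= 0:
        raise ValidationError(f"httkv must be > 0, got {httkv}")
    return ((httkv / REFERENCE_HTTKV) ** (1.0 / age) - 1.0) * 100.0


def class_from_rate(rate: float) -> str:
    """Map a theoretical growth rate to its class; intervals are
    left-closed/right-open, so a rate exactly on a threshold takes the upper
    class ([1.5, 3) -> 1B and so on)."""
    idx = int(np.searchsorted(CLASS_THRESHOLDS, rate, side="right"))
    return CLASS_NAMES[idx]


def mic_class(httkv: float, age: float, patient_id: str = "") -> MICRecord:
    """Classify a patient 1A-1E from htTKV and age."""
    rate = theoretical_growth_rate(httkv, age)
    return MICRecord(patient_id=patient_id, httkv=httkv, age=age,
                     theoretical_rate=rate, mic_class=class_from_rate(rate))


def add_mic_columns(patients: pd.DataFrame,
                    tkv_col: str = "tkv_at_start_ml",
                    height_col: str = "height_m",
                    age_col: str = "treatment_start_age") -> pd.DataFrame:
    """Append ``httkv``, ``mic_rate`` and ``mic_class`` columns."""
    out = patients.copy()
    recs = [mic_class(height_adjusted_tkv(t, h), a, pid)
            for pid, t, h, a in zip(out["patient_id"], out[tkv_col],
                                    out[height_col], out[age_col])]
    out["httkv"] = [r.httkv for r in recs]
    out["mic_rate"] = [r.theoretical_rate for r in recs]
    out["mic_class"] = [r.mic_class for r in recs]
    return out
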