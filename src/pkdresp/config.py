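"""Cohort simulation configuration.

``CohortConfig`` holds every distributional parameter of the synthetic ADPKD
cohort generator.  Defaults reproduce the published baseline characteristics of
a 32-patient tolvaptan-treated cohort: exponential kidney growth with
group-specific pre-treatment rates and treatment effects, per-sequence TKV
measurement noise, right-skewed baseline TKV and urine osmolality, and the
routine creatinine monitoring schedule (monthly for 18 months, then quarterly
to month 48).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
GROUPS = (RESPONDER, NON_RESPONDER)

#: quantile of the standard normal at 0.75, used to map an IQR to a lognormal sigma
_Z75 = 0.6744897501960817


def lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    """Sigma of a lognormal whose interquartile range is [q1, q3]."""
    if not 0 < q1 < q3:
        raise ValidationError(f"iqr must satisfy 0 < q1 < q3, got [{q1}, {q3}]")
    return math.log(q3 / q1) / (2 * _Z75)


@dataclass
class CohortConfig:
    """All simulator distribution parameters; ``seed`` fully determines output.

    Group-keyed fields map ``"responder"`` / ``"non-responder"`` to the group's
    parameter.  Growth rates are annual percent; deltas are percentage points
    per year (during minus pre); eGFR slopes are mL/min/1.73 m^2 per year.
    """

    n_patients: int = 32
    responder_fraction: float = 18 / 32

    # demographics
    age_mean: float = 42.0          # years, at treatment start
    age_sd: float = 9.0
    age_range: tuple[float, float] = (18.0, 70.0)
    male_fraction: float = 17 / 32
    height_mean: float = 1.70       # metres
    height_sd: float = 0.10
    height_range: tuple[float, float] = (1.40, 2.10)
    weight_mean: float = 75.0       # kg
    weight_sd: float = 16.0

    # baseline TKV: lognormal calibrated to median 1622 mL, IQR [1067, 2715]
    baseline_tkv_log_median: float = math.log(1622.0)
    baseline_tkv_log_sd: float = lognormal_sigma_from_iqr(1067.0, 2715.0)

    # kidney growth: pre-treatment rate and treatment-induced change, per group
    pre_growth_mean: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: 7.1, NON_RESPONDER: 3.7})
    pre_growth_sd: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: 3.6, NON_RESPONDER: 2.4})
    delta_growth_mean: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: -5.1, NON_RESPONDER: 2.4})
    delta_growth_sd: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: 2.5, NON_RESPONDER: 2.7})

    # MRI sampling
    sequence_cv: float = 0.013           # per-sequence multiplicative CV
    n_sequences_range: tuple[int, int] = (2, 5)
    pre_scan_window: float = 3.0         # years covered by pre-treatment MRIs
    during_scan_window: float = 3.0
    scans_per_window_range: tuple[int, int] = (3, 4)

    # spot urine osmolality (mOsm/kg): lognormal per group, from median/IQR
    uosm_median: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: 393.0, NON_RESPONDER: 194.0})
    uosm_iqr: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {RESPONDER: (256.0, 519.0),
                                 NON_RESPONDER: (167.0, 239.0)})

    # kidney function
    egfr_baseline_mean: float = 67.0     # mL/min/1.73 m^2
    egfr_baseline_sd: float = 27.0
    egfr_baseline_floor: float = 15.0
    egfr_slope: Mapping[str, float] = field(
        default_factory=lambda: {RESPONDER: -0.25, NON_RESPONDER: -0.40})
    egfr_resid_sd: float = 1.0           # visit-level noise on the eGFR scale

    # baseline liver function tests, lognormal around the cohort medians
    ast_median: float = 22.0
    ast_log_sd: float = lognormal_sigma_from_iqr(19.0, 27.0)
    alt_median: float = 22.0
    alt_log_sd: float = lognormal_sigma_from_iqr(18.0, 27.0)

    # exclusion-flag prevalences (0 by default: all simulated patients eligible)
    flag_rates: Mapping[str, float] = field(
        default_factory=lambda: {"interruption_gt_1_month": 0.0,
                                 "non_adherence": 0.0,
                                 "cyst_event": 0.0})

    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def egfr_months(self) -> list[int]:
        """Creatinine/eGFR visit schedule: months 1..18 monthly, then quarterly to 48."""
        return list(range(1, 19)) + list(range(21, 49, 3))

    def uosm_log_median(self, group: str) -> float:
        return math.log(self.uosm_median[group])

    def uosm_log_sd(self, group: str) -> float:
        q1, q3 = self.uosm_iqr[group]
        return lognormal_sigma_from_iqr(q1, q3)

    # ------------------------------------------------------------------
    def validate(self) -> "CohortConfig":
        """Raise :class:`ValidationError` naming the first invalid field."""
        if not isinstance(self.n_patients, (int,)) or self.n_patients < 0:
            raise ValidationError(f"n_patients must be a nonnegative integer, got {self.n_patients}")
        for name in ("responder_fraction", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("age_sd", "height_sd", "weight_sd", "baseline_tkv_log_sd",
                     "egfr_baseline_sd", "egfr_resid_sd", "sequence_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("pre_scan_window", "during_scan_window"):
            if getattr(self, name) < 1.0:
                raise ValidationError(
                    f"{name} must be >= 1 year (scan-span eligibility), got {getattr(self, name)}")
        for name in ("pre_growth_sd", "delta_growth_sd"):
            for g, v in getattr(self, name).items():
                if v < 0:
                    raise ValidationError(f"{name}[{g}] must be >= 0, got {v}")
        lo, hi = self.scans_per_window_range
        if lo < 2 or hi < lo:
            raise ValidationError(
                f"scans_per_window_range must satisfy 2 <= lo <= hi, got {self.scans_per_window_range}")
        slo, shi = self.n_sequences_range
        if slo < 1 or shi < slo:
            raise ValidationError(
                f"n_sequences_range must satisfy 1 <= lo <= hi, got {self.n_sequences_range}")
        for g, r in self.flag_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"flag_rates[{g}] must lie in [0, 1], got {r}")
        if not isinstance(self.seed, int):
            raise ValidationError(f"seed must be an integer, got {self.seed!r}")
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for YAML/JSON round-tripping
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(d)
        for name in ("age_range", "height_range", "n_sequences_range",
                     "scans_per_window_range"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = tuple(kwargs[name])
        if "uosm_iqr" in kwargs:
            kwargs["uosm_iqr"] = {g: tuple(v) for g, v in kwargs["uosm_iqr"].items()}
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        # allow either a flat mapping or a file with a `cohort:` section
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw = raw["cohort"]
        return cls.from_dict(raw)
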