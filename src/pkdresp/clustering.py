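"""Responder classification by exact one-dimensional k-means (k=2).

The per-patient change in annual TKV growth rate (during minus pre, in
percentage points per year) is clustered into two groups.  In one dimension
the globally optimal 2-partition is contiguous in sorted order, so it is found
by scanning all n-1 contiguous splits — no random initialisation, no seed
sensitivity.  The cluster with the lower mean change (the larger decrease in
growth rate) is labelled the responder group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguityError, DegenerateInputError, ValidationError

RESPONDER = "responder"
NON_RESPONDER = "non-responder"


@dataclass(frozen=True)
class ClusterResult:
    split_value: float          # midpoint of the gap between the two clusters
    cluster_means: tuple[float, float]   # (low mean, high mean)
    within_ss: float
    labels: tuple[int, ...]     # 0 = low cluster, 1 = high cluster, input order
    low_max: float              # largest member of the low cluster
    high_min: float             # smallest member of the high cluster


@dataclass(frozen=True)
class ResponderCall:
    patient_id: str
    pre_rate: float
    during_rate: float
    delta: float                # during - pre, percentage points per year
    label: str                  # "responder" | "non-responder"


def delta_growth_rate(pre_rate: float, during_rate: float) -> float:
    """Change in annual TKV growth rate: during minus pre (points per year)."""
    if not (np.isfinite(pre_rate) and np.isfinite(during_rate)):
        raise ValidationError(f"rates must be finite, got ({pre_rate}, {during_rate})")
    return float(during_rate) - float(pre_rate)


def kmeans1d_exact(values: Sequence[float], k: int = 2) -> ClusterResult:
    """Globally optimal 1-D 2-means by exhaustive scan of contiguous splits.

    Every candidate partition keeps the i smallest values in the low cluster;
    within-cluster sum of squares is evaluated via prefix sums and the minimum
    taken (first minimum on ties, hence deterministic).
    """
    if k != 2:
        raise ValidationError(f"only k=2 is supported, got k={k}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError(f"need >= 2 values, got {x.size}")
    if np.unique(x).size < 2:
        raise DegenerateInputError("all values identical; no 2-cluster structure")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def ss(lo: int, hi: int) -> float:  # within-SS of xs[lo:hi]
        m = hi - lo
        s = csum[hi] - csum[lo]
        return (csq[hi] - csq[lo]) - s * s / m

    costs = np.array([ss(0, i) + ss(i, n) for i in range(1, n)])
    i = int(np.argmin(costs)) + 1   # size of the low cluster
    labels_sorted = np.zeros(n, dtype=int)
    labels_sorted[i:] = 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    low, high = xs[:i], xs[i:]
    return ClusterResult(
        split_value=float((low[-1] + high[0]) / 2.0),
        cluster_means=(float(low.mean()), float(high.mean())),
        within_ss=float(costs[i - 1]),
        labels=tuple(int(v) for v in labels),
        low_max=float(low[-1]),
        high_min=float(high[0]),
    )


def assign_response_labels(result: ClusterResult,
                           patient_ids: Sequence[str],
                           pre_rates: Sequence[float],
                           during_rates: Sequence[float]) -> list[ResponderCall]:
    """Map clusters to clinical labels: lower mean change -> responders.

    Raises :class:`AmbiguityError` when the cluster means coincide (no
    direction to the split).  The gap between clusters is available on the
    :class:`ClusterResult` as ``(low_max, high_min)``.
    """
    low_mean, high_mean = result.cluster_means
    if low_mean == high_mean:
        raise AmbiguityError("cluster means are equal; responder direction undefined")
    # low cluster = larger decrease in growth rate = responders
    name = {0: RESPONDER, 1: NON_RESPONDER}
    calls = []
    for pid, pre, dur, lab in zip(patient_ids, pre_rates, during_rates, result.labels):
        calls.append(ResponderCall(patient_id=str(pid), pre_rate=float(pre),
                                   during_rate=float(dur),
                                   delta=delta_growth_rate(pre, dur),
                                   label=name[lab]))
    return calls


def classify_cohort(growth_fits: pd.DataFrame) -> tuple[ClusterResult, pd.DataFrame]:
    """Convenience wrapper over a growth_fits table (patient_id, window,
    annual_rate): pivots to per-patient pre/during rates, clusters the deltas,
    and returns the responder_calls table."""
    wide = growth_fits.pivot(index="patient_id", columns="window",
                             values="annual_rate")
    if not {"pre", "during"}.issubset(wide.columns):
        raise ValidationError("growth_fits must contain both 'pre' and 'during' windows")
    wide = wide.dropna(subset=["pre", "during"]).sort_index()
    deltas = (wide["during"] - wide["pre"]).to_numpy()
    result = kmeans1d_exact(deltas)
    calls = assign_response_labels(result, wide.index.to_list(),
                                   wide["pre"].to_numpy(), wide["during"].to_numpy())
    table = pd.DataFrame([{"patient_id": c.patient_id, "pre_rate": c.pre_rate,
                           "during_rate": c.during_rate, "delta": c.delta,
                           "label": c.label} for c in calls])
    return result, table
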