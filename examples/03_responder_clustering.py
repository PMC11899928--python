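"""Classify responders by exact 1-D k-means on the change in growth rate.

In one dimension the optimal 2-means partition is contiguous in sorted
order, so the global optimum is found deterministically by scanning all
splits; the cluster whose mean change is lower (the bigger slowdown in
kidney growth) is the responder group.
"""

import pandas as pd

from pkdresp import CohortConfig, simulate_cohort, split_pre_during
from pkdresp.clustering import classify_cohort

cohort = simulate_cohort(CohortConfig(n_patients=32, seed=0))
rows = []
for p in cohort:
    pre, dur = split_pre_during(p.scans, p.treatment_start_age)
    rows += [{"patient_id": p.patient_id, "window": f.window,
              "annual_rate": f.annual_rate} for f in (pre, dur)]
fits = pd.DataFrame(rows)

result, calls = classify_cohort(fits)
print(f"split at {result.split_value:.2f} points/yr; cluster means "
      f"{result.cluster_means[0]:.2f} and {result.cluster_means[1]:.2f}")
print(calls["label"].value_counts().to_string())

truth = {p.patient_id: p.true_group for p in cohort}
agree = (calls["label"] == calls["patient_id"].map(truth)).mean()
print(f"\nagreement with generative truth: {agree:.0%}")
print("The gap between the largest responder change and the smallest")
print("non-responder change is the natural separation the clustering finds.")
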