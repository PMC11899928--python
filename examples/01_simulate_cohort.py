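"""Generate a synthetic ADPKD cohort and look at its structure.

Each patient carries a piecewise-exponential kidney-volume trajectory (one
growth rate before tolvaptan start, another during treatment), serial MRI
visits with per-sequence measurement noise, and a lab panel with an eGFR
series back-converted to serum creatinine.
"""

import numpy as np

from pkdresp import CohortConfig, cohort_to_frames, simulate_cohort

cfg = CohortConfig(n_patients=32, seed=0)
cohort = simulate_cohort(cfg)
scans, patients, labs = cohort_to_frames(cohort)

n_resp = (patients["true_group"] == "responder").sum()
print(f"patients: {len(patients)}  (responders: {n_resp}, "
      f"non-responders: {len(patients) - n_resp})")
print(f"scan rows (one per pulse sequence): {len(scans)}")
print(f"lab visits per patient: {labs.groupby('patient_id').size().iloc[0]}")

pre = patients.groupby("true_group")["true_pre_rate"].agg(["mean", "std"])
print("\ntrue pre-treatment growth rate (%/yr) by group:")
print(pre.round(2))
print("\nThe responder group grows faster before treatment (about 7 vs 4 %/yr),")
print("which is the structure the downstream classifier should rediscover.")
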