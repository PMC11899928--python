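"""Fit pre- and during-treatment TKV growth rates for one patient.

Scans are collapsed to mean TKV over the sequences covering both kidneys;
log TKV is regressed on age separately on each side of treatment start, and
the slope is annualized as a compound percent growth rate.
"""

from pkdresp import CohortConfig, simulate_cohort, split_pre_during

cohort = simulate_cohort(CohortConfig(n_patients=4, seed=2))
for p in cohort:
    pre, dur = split_pre_during(p.scans, p.treatment_start_age)
    print(f"{p.patient_id} ({p.true_group:>13}): "
          f"pre {pre.annual_rate:5.1f} %/yr (true {p.true_pre_rate:5.1f}), "
          f"during {dur.annual_rate:5.1f} %/yr (true {p.true_during_rate:5.1f})")

print("\nWith 1.3% per-sequence measurement noise the fitted rates track the")
print("generative rates to within a couple of percentage points per year; a")
print("responder shows a clear drop from the pre to the during rate.")
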