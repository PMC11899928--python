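"""Compare eGFR decline slopes between responders and non-responders.

Change in eGFR from treatment start is regressed on time per group; the
pooled model's group-by-time interaction tests whether the declines differ.
"""

import pandas as pd

from pkdresp import (CohortConfig, fit_group_slopes, simulate_cohort,
                     slope_excess_percent)

cohort = simulate_cohort(CohortConfig(n_patients=500, seed=4))
rows = [{"patient_id": p.patient_id, "months_since_start": 0.0,
         "egfr": p.egfr_baseline} for p in cohort]
rows += [{"patient_id": p.patient_id, "months_since_start": pt.months_since_start,
          "egfr": pt.egfr} for p in cohort for pt in p.egfr_series]
labels = pd.Series({p.patient_id: p.true_group for p in cohort})

cmp = fit_group_slopes(pd.DataFrame(rows), labels)
for g, gs in cmp.slopes.items():
    print(f"{g:>13}: {gs.slope:+.3f} mL/min/1.73m2 per year "
          f"(95% CI {gs.ci[0]:+.3f} to {gs.ci[1]:+.3f})")
print(f"interaction p = {cmp.interaction_p:.2g}")
print(f"non-responder decline exceeds responder decline by "
      f"{slope_excess_percent(cmp.slopes['responder'].slope, cmp.slopes['non-responder'].slope):.0f}%")
print("\nKidney function falls in both groups, but faster in patients whose")
print("kidney growth did not slow on treatment (generative truth: -0.25 vs")
print("-0.40 per year, a 60% excess).")
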