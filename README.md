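# pkdresp

Individual-patient assessment of tolvaptan efficacy in autosomal dominant
polycystic kidney disease (ADPKD), built for nephrology and imaging
researchers who track total kidney volume (TKV) on serial MRI.

Randomized trials established that tolvaptan slows kidney growth on average,
but they do not say whether a *particular* patient is benefiting. With deep
learning segmentation, TKV can be measured with per-sequence variability
around 1.3%, which makes per-patient growth-rate estimation meaningful. This
package implements that analysis end to end:

1. **Growth rates.** Each MRI visit is collapsed to the mean TKV over the
   pulse sequences covering both kidneys. Under exponential growth
   `TKV(t) = a·e^{b·t}`, ordinary least squares of `ln TKV` on age gives the
   slope `b` separately before and during treatment; the annualized rate is
   `(e^b − 1)·100` %/yr.
2. **Responder classification.** The per-patient change in growth rate,
   `Δ = rate_during − rate_pre` (percentage points per year), is clustered by
   **exact one-dimensional k-means (k=2)** — the global optimum over all
   contiguous splits of the sorted values, with no random initialisation.
   The cluster with the lower mean Δ (larger slowdown) is the responder group.
3. **Group statistics.** Shapiro–Wilk-routed univariate tests
   (t / Mann–Whitney / chi-squared) with Benjamini–Hochberg correction; a
   multivariate logistic model of responder status (non-responder coded 1)
   with Wald intervals, variance-inflation factors and bidirectional
   AIC-guided selection; two-way random-effects absolute-agreement ICC for
   interobserver TKV agreement.
4. **Kidney function.** eGFR via the race-free 2021 CKD-EPI creatinine
   equation; per-group decline slopes of ΔeGFR on time with a group×time
   interaction test.
5. **Power.** Paired-design Cohen's d and the sample size
   `n = ⌊((z_{1−α/2} + z_{1−β})/d)²⌋`, with a Monte-Carlo paired-t check.
6. **Synthetic cohorts.** Because the underlying patient data are not
   public, a seeded generator produces cohorts with the published structure
   (group-specific growth rates and treatment effects, lognormal baseline
   TKV and urine osmolality, monthly-then-quarterly creatinine schedule), so
   the whole pipeline is testable and reproducible.

## Worked example

```python
from pkdresp import CohortConfig, simulate_cohort, split_pre_during
from pkdresp.clustering import classify_cohort
import pandas as pd

cohort = simulate_cohort(CohortConfig(n_patients=32, seed=0))
rows = []
for p in cohort:
    pre, dur = split_pre_during(p.scans, p.treatment_start_age)
    rows += [{"patient_id": p.patient_id, "window": f.window,
              "annual_rate": f.annual_rate} for f in (pre, dur)]
result, calls = classify_cohort(pd.DataFrame(rows))
print(result.split_value, calls["label"].value_counts().to_dict())
```

prints

```
-2.344663249089374 {'responder': 18, 'non-responder': 14}
```

— the clustering finds its natural split at −2.3 percentage points per year
and calls 18 of the 32 synthetic patients responders, 94% of them matching
the generative group labels (`examples/03_responder_clustering.py` shows the
full output). The other scripts under `examples/` walk through simulation,
growth fitting, eGFR slopes, power planning and the full pipeline; the same
stages are available from the shell:

```bash
pkdresp run --seed 0 --outdir pkdresp_run
pkdresp power --alpha 0.01 --power 0.9
```

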