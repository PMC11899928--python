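# Methods

## Growth-rate model

TKV is modelled as exponential in age within each treatment window:
`TKV(age) = a · e^{b·(age − ā)}`, fitted by ordinary least squares of
`ln TKV` on age (two parameters, ages centred at the window mean `ā` for
conditioning; the slope is unchanged). Each scan contributes one point: the
arithmetic mean TKV over the pulse sequences that image both kidneys in
their entirety; sequences truncating a kidney are excluded, and a scan with
no qualifying sequence is a missing-data error, not a zero.

The reported rate is the compound annual rate `(e^b − 1)·100` %/yr rather
than `b·100`. The two differ by under 0.2 points at typical ADPKD rates
(≤6 %/yr); the compound convention matches how annual kidney growth is
quoted clinically, and switching to the log-slope convention is a one-line
change in `growth.fit_exponential_growth`. Fits carry the RMS of log
residuals as a diagnostic. No weighting by the number of sequences per scan
is applied (no principled weight is available without a per-sequence error
model), and no outlier rejection is performed.

Window assignment: a scan exactly at the treatment start age belongs to the
pre-treatment window, since the drug cannot have acted at initiation. Ages,
not calendar dates, are the regression abscissa. Eligibility mirrors the
clinical screen — at least two scans spanning at least one year on each side
of treatment start — plus chart-review flags (treatment interruption longer
than a month, non-adherence, cyst rupture/aspiration) that are *inputs*;
the package never infers them.

## Responder classification

The primitive is the signed change `Δ = rate_during − rate_pre` in
percentage points per year (an "absolute reduction of 2%" is `Δ = −2`).
For k = 2 in one dimension the optimal k-means partition is contiguous in
sorted order, so `kmeans1d_exact` scans all n−1 contiguous splits with
prefix sums and returns the global minimum of within-cluster sum of squares
— deterministic, seed-free, and verified in tests against brute-force
enumeration of *all* 2-partitions. Lloyd-style k-means (scikit-learn) serves
only as a cross-check in the test suite. The cluster with the lower mean Δ
is labelled the responder group; equal cluster means raise an ambiguity
error rather than guessing. k is fixed at 2; no model selection over k.

## Imaging classification

Height-adjusted TKV (htTKV = TKV/height, mL/m) and age yield a theoretical
annual growth rate `((htTKV/150)^{1/age} − 1)·100`, cut at 1.5/3/4.5/6 %/yr
into classes 1A–1E. The 150 mL/m reference and the thresholds are externally
sourced constants of the classification, not derived in this package. Rate
intervals are left-closed/right-open (`[1.5, 3) → 1B`, …) — a fixed
convention, tested at the boundaries, since the source states thresholds
only as ranges. htTKV below 150 gives a nonpositive rate and class 1A by
construction. Atypical/asymmetric morphology (class 2) is out of scope; the
eligibility screen already assumes symmetric disease.

## Statistical battery

* **Routing.** Continuous variables use Student's t (equal variances) when
  both groups pass Shapiro–Wilk at the conventional 0.05, else Mann–Whitney
  (exact when the smaller group has n < 8 and no ties, normal approximation
  with tie correction otherwise). Categorical variables use chi-squared
  without continuity correction; the imaging class is compared as a single
  5-level categorical. Summaries follow the routing: mean ± SD when normal,
  median [IQR] otherwise.
* **FDR.** Benjamini–Hochberg step-up over the whole battery (statsmodels).
  Note BH is *not* idempotent in general (re-adjusting an adjusted vector
  can increase values), so the tested invariants are adjusted ≥ raw, cap at
  1, permutation equivariance, and order preservation.
* **Logistic model.** Outcome coded non-responder = 1, responder = 0, so
  that the responder-associated predictors (baseline growth rate, urine
  osmolality) carry negative coefficients; `positive_class` flips the
  coding. Wald SEs and ±1.96·SE intervals; VIF per predictor from auxiliary
  OLS regressions with intercept (for two predictors both VIFs equal
  1/(1−r²)). Perfect separation is flagged and the fit reported with a
  warning rather than raised. Model selection is bidirectional AIC-greedy
  from the full candidate set (continuous variables with univariate raw
  p < 0.05, plus age and sex), deterministic tie-break by candidate order,
  falling back to intercept-only when nothing improves. Under AIC a
  pure-noise candidate survives with probability ≈ P(χ²₁ > 2) ≈ 0.16, so
  recovery tests assert that the true signal carriers are contained in the
  selected set, not that the set is exact.
* **ICC.** Interobserver agreement uses the single-measure two-way
  random-effects absolute-agreement form ICC(2,1), computed from ANOVA mean
  squares: `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`. Absolute
  agreement (not consistency) is the clinically relevant question for raters
  measuring the same kidneys; the implementation is cross-checked against
  pingouin's ICC(A,1) in tests. Missing cells are an error; no imputation.

## eGFR trajectory

eGFR comes from the race-free 2021 CKD-EPI creatinine equation
(142 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.200 · 0.9938^age · 1.012 if female;
κ = 0.7/0.9, α = −0.241/−0.302 for women/men). Its exact piecewise inverse
is provided so simulated eGFR can be expressed as creatinine. ΔeGFR is
referenced to the month-0 value (falling back to the earliest visit), making
all slopes invariant to constant shifts. Group slopes are separate OLS fits
of ΔeGFR on years since start; the difference test is the group×time
interaction of a pooled OLS on the same points — matching a pooled-scatter
presentation; per-patient random-slope models are deliberately not the
default. Slopes are reported per year regardless of visit spacing. A
4-month binning is used only for plotting; fits always use raw visit times.

## Power calculation

Planning inputs: growth-rate mean falling from 5.5 to 2.8 %/yr with a 3 %/yr
SD of the within-patient change, i.e. paired Cohen's d = (5.5 − 2.8)/3 = 0.9.
The default convention — two-sided normal approximation with truncation —
gives n = ⌊((z₀.₉₉₅ + z₀.₉₀)/0.9)²⌋ = ⌊18.37⌋ = 18, and is the only
sidedness/rounding combination that lands on 18; the one-sided and
ceil/nearest variants (17–19) are exposed as options. The accompanying
Monte-Carlo check simulates paired t-tests at the returned n: the exact
noncentral-t power at n = 18, α = 0.01 is ≈ 0.81, i.e. the normal
approximation is optimistic at this size — the simulation reports the honest
number rather than the nominal 90%.

## Synthetic cohort generator

The generator emulates the observed cohort structure, not the imaging:

| parameter | default | source of the value |
|---|---|---|
| n, responder fraction | 32, 18/32 | observed cohort split |
| age at start | 42 ± 9 y, truncated [18, 70] | cohort mean ± SD; physiologic bounds |
| height | 1.70 ± 0.10 m, truncated [1.4, 2.1] | cohort; physiologic bounds |
| baseline TKV | lognormal, median 1622 mL, σ from IQR [1067, 2715] | right-skewed, reported as median/IQR |
| pre-treatment growth | N(7.1, 3.6²) resp / N(3.7, 2.4²) non-resp %/yr | group means ± SD |
| growth-rate change Δ | N(−5.1, 2.5²) resp / N(+2.4, 2.7²) non-resp | group means ± SD |
| sequence noise | multiplicative lognormal, CV 1.3%, independent per sequence | best-case deep-learning measurement variability |
| sequences per scan | 2–5 | typical abdominal MRI protocols |
| scans per window | 3–4 over a 3-year window each side | ~3-year imaging follow-up with roughly annual MRI |
| urine osmolality | lognormal per group, medians 393/194, σ from IQRs | group medians/IQRs |
| baseline eGFR | 67 ± 27, floored at 15 | cohort mean ± SD; dialysis-free floor |
| eGFR slope | −0.25 resp / −0.40 non-resp mL/min/1.73 m²/yr | group decline slopes |
| eGFR visit noise | SD 1.0 | visit-level noise consistent with the pooled slope SE ≈ 0.04 over ~900 points |
| creatinine schedule | months 1–18 monthly, then quarterly to 48 | routine tolvaptan monitoring |

Group sizes use exact allocation (`round(n·fraction)`, then shuffled) so
small test cohorts have deterministic composition. TKV trajectories are
piecewise exponential and continuous at treatment start; every simulated
measurement is the trajectory value times mean-one lognormal noise, so with
CV = 0 the fitter must recover the generative rates to numerical precision
(asserted at 1e-9 %/yr). The eGFR series is generated directly on the eGFR
scale and back-converted to creatinine through the exact CKD-EPI inverse.
One `numpy` Generator seeded from `config.seed` drives everything; equal
seeds give byte-identical output tables.

What the generator does **not** emulate: within-patient biological
fluctuation of growth rate over time (rates are constant within a window),
correlated sequence errors within a scan, dropout/irregular visit
compliance, measured confounders of eGFR (blood pressure, glycaemia,
medications), and any association between growth rate and osmolality beyond
their shared group label. Passing recovery tests therefore show the
estimators are correct under the stated noise model, not that the clinical
findings would replicate in new patients.

A note on the eGFR decline defaults: −0.25/−0.40 mL/min/1.73 m² per year is
roughly an order of magnitude slower than typical ADPKD cohorts, and the
quoted ±SE does not match the quoted CI half-widths; the values are used
verbatim as generator defaults, with this tension recorded rather than
"corrected".

## Numerical and degenerate-input choices

* Growth fit: requires ≥2 points with distinct ages; all-equal ages is an
  insufficient-data error. Ages are mean-centred before `polyfit`.
* Clustering: all-identical values is a degenerate-input error; ties in the
  split cost are broken by the first (smallest-low-cluster) optimum.
* Truncated normals are rejection-sampled (bounds are several SDs out, so
  retries are rare and seeded).
* eGFR floor of 1.0 mL/min/1.73 m² keeps simulated values positive.
* Stepwise selection treats AIC improvements below 1e-12 as ties (no move).

## Problem sizes in tests

The suite exercises the law-of-large-numbers and slope-recovery properties
on a shared 2000-patient cohort, logistic CI coverage on 100 replicates at
n = 5000, selection recovery on 25 replicates at n = 2000, osmolality power
on 200 replicates of 18-vs-14 draws, and fitter calibration on 1000
simulated 3-scan series — sizes chosen to hold Monte-Carlo error comfortably
below the asserted margins while keeping the default run fast.

## Known limitations

* Per-kidney (left/right) trajectories, Bayesian growth models, and
  bootstrap stability of the clustering are out of scope.
* No Firth correction for separation; no multiple imputation; confounder
  adjustment for the eGFR comparison is deliberately omitted.
* The eligibility flags cannot be derived from the data tables; real use
  requires chart review to supply them.
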