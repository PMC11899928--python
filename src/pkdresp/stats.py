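"""Group statistics for the responder / non-responder comparison.

Covers the univariate battery (Shapiro-Wilk-routed t or Mann-Whitney tests
for continuous variables, chi-squared for categorical, Benjamini-Hochberg
correction across the battery), the multivariate logistic response model with
Wald intervals and variance-inflation factors, bidirectional AIC-guided model
selection, and the two-way random-effects absolute-agreement intraclass
correlation for interobserver TKV agreement.

Outcome coding for the logistic model: non-responder = 1, responder = 0, so
that higher baseline growth rate and higher urine osmolality (responder
features) carry negative coefficients; ``positive_class`` flips the coding.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import PKDRespError, ValidationError

SHAPIRO_ALPHA = 0.05  # conventional normality threshold for test routing
T_TEST = "t"
MANN_WHITNEY = "mann-whitney"
CHI_SQUARED = "chi-squared"


# ---------------------------------------------------------------------------
# univariate battery


@dataclass(frozen=True)
class VariableComparison:
    variable: str
    kind: str                       # continuous | categorical
    summary: Mapping[str, str]      # group -> "mean +/- sd" or "median [q1, q3]"
    test: str
    p_raw: float
    p_bh: float | None = None


def route_test(values_by_group: Mapping[str, Sequence], kind: str,
               shapiro_alpha: float = SHAPIRO_ALPHA) -> str:
    """Choose the comparison test for one variable.

    Continuous variables use Student's t-test when both groups pass
    Shapiro-Wilk normality (p > alpha), else Mann-Whitney; categorical
    variables use the chi-squared test on the contingency table.
    """
    if kind == "categorical":
        return CHI_SQUARED
    if kind != "continuous":
        raise ValidationError(f"variable kind must be continuous|categorical, got {kind!r}")
    for g, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 3:
            raise PKDRespError(
                f"group {g!r} has {v.size} observations; >= 3 needed for normality routing")
        if np.ptp(v) == 0:
            return MANN_WHITNEY  # constant sample: Shapiro undefined, not normal-like
        if sps.shapiro(v).pvalue <= shapiro_alpha:
            return MANN_WHITNEY
    return T_TEST


def _mann_whitney_method(a: np.ndarray, b: np.ndarray) -> str:
    # exact for small samples without ties, normal approximation otherwise
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    return "exact" if (min(a.size, b.size) < 8 and not ties) else "asymptotic"


def _test_continuous(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == T_TEST:
        return float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method=_mann_whitney_method(a, b))
    return float(res.pvalue)


def _test_categorical(a: Sequence, b: Sequence) -> float:
    levels = sorted(set(a) | set(b), key=str)
    table = np.array([[list(a).count(l) for l in levels],
                      [list(b).count(l) for l in levels]])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 1.0  # a single observed level carries no distributional signal
    return float(sps.chi2_contingency(table, correction=False).pvalue)


def _summarise(vals: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(vals):.3g} ± {np.std(vals, ddof=1):.3g}"
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return f"{med:.4g} [{q1:.4g}, {q3:.4g}]"


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError(f"p-values must lie in [0, 1], got {p_values}")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups_univariate(table: pd.DataFrame, labels: pd.Series,
                              variables: Mapping[str, str]
                              ) -> list[VariableComparison]:
    """Run the routed test per variable and BH-adjust over the whole battery.

    ``variables`` maps column name -> "continuous" | "categorical".  All-missing
    variables are dropped with a warning rather than failing the battery.
    """
    if isinstance(labels, pd.Series) and labels.index.equals(table.index):
        labels = labels.loc[table.index]
    else:
        labels = pd.Series(np.asarray(labels), index=table.index)
    groups = sorted(labels.unique(), key=str)
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {groups}")
    comparisons: list[VariableComparison] = []
    for var, kind in variables.items():
        col = table[var]
        if col.isna().all():
            warnings.warn(f"variable {var!r} is entirely missing; excluded from battery")
            continue
        by_group = {g: col[labels == g].dropna() for g in groups}
        if kind == "continuous":
            arrs = {g: v.to_numpy(dtype=float) for g, v in by_group.items()}
            test = route_test(arrs, kind)
            p = _test_continuous(arrs[groups[0]], arrs[groups[1]], test)
            normal = test == T_TEST
            summary = {g: _summarise(arrs[g], normal) for g in groups}
        else:
            test = CHI_SQUARED
            p = _test_categorical(by_group[groups[0]], by_group[groups[1]])
            summary = {g: ", ".join(f"{l}: {list(by_group[g]).count(l)}"
                                    for l in sorted(set(col.dropna()), key=str))
                       for g in groups}
        comparisons.append(VariableComparison(variable=var, kind=kind,
                                              summary=summary, test=test, p_raw=p))
    adjusted = bh_adjust([c.p_raw for c in comparisons])
    return [VariableComparison(variable=c.variable, kind=c.kind, summary=c.summary,
                               test=c.test, p_raw=c.p_raw, p_bh=float(q))
            for c, q in zip(comparisons, adjusted)]


def comparisons_to_frame(comparisons: Sequence[VariableComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"variable": c.variable, "kind": c.kind, "test": c.test,
               "p_raw": c.p_raw, "p_bh": c.p_bh}
        for g, s in c.summary.items():
            row[f"summary_{g}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multivariate logistic model


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    coef: float
    se: float
    ci: tuple[float, float]
    p: float
    vif: float | None  # None for the intercept


@dataclass(frozen=True)
class LogisticModelFit:
    outcome_coding: str
    terms: tuple[LogisticTerm, ...]
    aic: float
    n: int
    separation_flag: bool = False  # Wald CIs unreliable when True


def variance_inflation_factors(X: pd.DataFrame) -> dict[str, float]:
    """VIF per predictor from auxiliary OLS regressions (with intercept)."""
    vifs = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        exog = sm.add_constant(others.to_numpy()) if others.shape[1] else \
            np.ones((len(X), 1))
        r2 = sm.OLS(X[col].to_numpy(), exog).fit().rsquared
        vifs[col] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def fit_logistic_response_model(outcome_labels: Sequence, predictors: pd.DataFrame,
                                positive_class: str = "non-responder"
                                ) -> LogisticModelFit:
    """Maximum-likelihood logistic fit with Wald SEs/CIs and per-term VIF.

    ``positive_class`` is coded 1.  Perfect separation is flagged (the fit is
    still reported, with a warning and CIs marked unreliable) rather than
    raised.
    """
    y = np.asarray([1.0 if l == positive_class else 0.0 for l in outcome_labels])
    if predictors.shape[1] < 1:
        raise ValidationError("at least one predictor required")
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome is constant; logistic model undefined")
    for col in predictors.columns:
        if np.ptp(predictors[col].to_numpy(dtype=float)) == 0:
            raise ValidationError(f"predictor {col!r} is constant")
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # PerfectSeparationError in some statsmodels versions
            separation = True
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=25)
        for w in caught:
            if "separat" in str(w.message).lower() or "converge" in str(w.message).lower():
                separation = True
    if separation:
        warnings.warn("possible separation/non-convergence: Wald CIs unreliable")
    vifs = variance_inflation_factors(predictors.astype(float))
    z = sps.norm.ppf(0.975)
    terms = []
    for name in X.columns:
        coef = float(fit.params[name])
        se = float(fit.bse[name])
        terms.append(LogisticTerm(
            name=str(name), coef=coef, se=se,
            ci=(coef - z * se, coef + z * se),
            p=float(fit.pvalues[name]),
            vif=None if name == "const" else vifs[name]))
    return LogisticModelFit(outcome_coding=f"{positive_class}=1",
                            terms=tuple(terms), aic=float(fit.aic),
                            n=int(len(y)), separation_flag=separation)


def stepwise_aic_select(outcome_labels: Sequence, data: pd.DataFrame,
                        candidates: Sequence[str],
                        positive_class: str = "non-responder"
                        ) -> tuple[list[str], list[dict]]:
    """Bidirectional AIC-greedy selection over ``candidates`` (fixed order ties).

    Starts from the full candidate set; at each step considers dropping any
    included term or adding any excluded one, takes the move with the lowest
    AIC if it improves, and stops otherwise.  Returns the selected predictor
    list (possibly empty: intercept-only) and the AIC trail.
    """
    y = np.asarray([1.0 if l == positive_class else 0.0 for l in outcome_labels])

    def aic_of(subset: tuple[str, ...]) -> float:
        X = sm.add_constant(data[list(subset)].astype(float), has_constant="add") \
            if subset else pd.DataFrame({"const": np.ones(len(y))}, index=data.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return float(sm.Logit(y, X).fit(disp=0, maxiter=200).aic)
            except Exception:
                return float("inf")

    current = tuple(candidates)
    trail = [{"model": list(current), "aic": aic_of(current)}]
    while True:
        best_move, best_aic = None, trail[-1]["aic"]
        moves = [tuple(t for t in current if t != drop) for drop in current]
        moves += [current + (add,) for add in candidates if add not in current]
        for m in moves:
            a = aic_of(m)
            if a < best_aic - 1e-12:
                best_move, best_aic = m, a
        if best_move is None:
            break
        current = best_move
        trail.append({"model": list(current), "aic": best_aic})
    # fall back to intercept-only if it beats every candidate model
    if aic_of(()) < trail[-1]["aic"] - 1e-12:
        current = ()
        trail.append({"model": [], "aic": aic_of(())})
    return list(current), trail


# ---------------------------------------------------------------------------
# interobserver agreement


@dataclass(frozen=True)
class ICCResult:
    icc_value: float
    form: str         # "ICC(2,1)" two-way random effects, absolute agreement
    n_subjects: int
    n_raters: int


def icc_agreement(ratings) -> ICCResult:
    """Single-measure absolute-agreement ICC, two-way random effects (ICC(2,1)).

    ``ratings`` is a complete subjects x raters matrix.  Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValidationError(f"ratings must be >=2 subjects x >=2 raters, got {R.shape}")
    if np.any(np.isnan(R)):
        raise PKDRespError("ratings matrix has missing cells; no imputation performed")
    n, k = R.shape
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((R - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise PKDRespError("zero variance in ratings; ICC undefined")
    return ICCResult(icc_value=float((msr - mse) / denom), form="ICC(2,1)",
                     n_subjects=n, n_raters=k)
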