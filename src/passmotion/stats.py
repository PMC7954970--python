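"""Cohort matching, descriptives, effect sizes and stature-adjusted regressions.

This is the statistical stage of the pipeline: match a comparison cohort to a
reference cohort on age, sex and BMI; describe every parameter per cohort
(mean, SD, CV, Shapiro-Wilk); compare cohorts with pooled-variance t-tests
and Cohen's d; and fit standardized multiple linear regressions of each
parameter on group, height and weight.  No multiplicity correction is applied
anywhere — the comparison is exploratory by design — and non-normality is
reported but never gates the t-tests.

Group coding is 0 = reference (Japanese), 1 = comparison (German), so effect
signs are comparison-minus-reference throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .skeleton import PARAMETER_NAMES, PARAMETER_UNITS, SubjectRecord

__all__ = [
    "MatchingError",
    "TTestResult",
    "RegressionResult",
    "SexRatioTest",
    "match_cohorts",
    "describe",
    "summary_cohens_d",
    "independent_t",
    "sex_chi2",
    "adjusted_regression",
    "build_report",
    "ALPHA",
]

#: Significance threshold used for report marking.
ALPHA = 0.05

#: Condition-number threshold above which predictors are flagged collinear.
COLLINEARITY_CONDITION_LIMIT = 1e8


class MatchingError(ValueError):
    """Cohort matching cannot satisfy the reference composition."""


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

def match_cohorts(candidates: Sequence[SubjectRecord],
                  reference: Sequence[SubjectRecord],
                  age_range: tuple[float, float] = (20.0, 40.0),
                  bmi_range: tuple[float, float] = (18.0, 29.0),
                  ) -> list[SubjectRecord]:
    """Select an age/sex/BMI-matched subset of ``candidates``.

    Three steps: filter candidates to the age window, then to the BMI window,
    then fill each sex stratum of the reference by greedy nearest-neighbour
    selection on BMI, breaking BMI ties in favour of the shorter (then
    lighter) candidate — matching toward a smaller-statured reference group.
    """
    reference = list(reference)
    if not reference:
        raise MatchingError("reference cohort is empty")
    eligible = [c for c in candidates
                if age_range[0] <= c.age <= age_range[1]
                and bmi_range[0] <= c.bmi <= bmi_range[1]]
    selected: list[SubjectRecord] = []
    for sex in ("F", "M"):
        refs = [r for r in reference if r.sex == sex]
        pool = [c for c in eligible if c.sex == sex]
        if len(pool) < len(refs):
            raise MatchingError(
                f"insufficient candidates in sex stratum {sex}: "
                f"need {len(refs)}, have {len(pool)} after age/BMI filters")
        used: set[str] = set()
        for ref in refs:
            best = min(
                (c for c in pool if c.subject_id not in used),
                key=lambda c: (abs(c.bmi - ref.bmi), c.height_cm, c.weight_kg),
            )
            used.add(best.subject_id)
            selected.append(best)
    return selected


# --------------------------------------------------------------------------
# Descriptives
# --------------------------------------------------------------------------

def describe(table: pd.DataFrame, cohorts: pd.Series) -> pd.DataFrame:
    """Per-parameter, per-cohort descriptives.

    Returns one row per (parameter, cohort): n, mean, sample SD (n-1),
    CV = SD/mean (undefined when mean <= 0), range, and the Shapiro-Wilk
    statistic/p with a ``normal`` flag at p > 0.05.
    """
    cohorts = cohorts.reindex(table.index)
    rows = []
    for name in table.columns:
        for cohort in pd.unique(cohorts.dropna()):
            values = table.loc[cohorts == cohort, name].dropna().to_numpy(float)
            row = {"parameter": name, "cohort": cohort, "n": int(values.size)}
            if values.size < 2:
                row.update({"mean": np.nan, "sd": np.nan, "cv": np.nan,
                            "min": np.nan, "max": np.nan,
                            "shapiro_w": np.nan, "shapiro_p": np.nan,
                            "normal": False, "flag": "fewer than 2 observations"})
                rows.append(row)
                continue
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1))
            w, p = sps.shapiro(values)
            row.update({
                "mean": mean, "sd": sd,
                "cv": sd / mean if mean > 0 else np.nan,
                "min": float(values.min()), "max": float(values.max()),
                "shapiro_w": float(w), "shapiro_p": float(p),
                "normal": bool(p > ALPHA),
                "flag": "" if mean > 0 else "CV undefined (mean <= 0)",
            })
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Effect sizes and tests
# --------------------------------------------------------------------------

def summary_cohens_d(mean1: float, sd1: float, n1: int,
                     mean2: float, sd2: float, n2: int) -> float:
    """Cohen's d from group summary moments, pooled SD with n-1 weights.

    ``d = (mean2 - mean1) / s_pooled`` with
    ``s_pooled = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))``;
    for equal group sizes this reduces to ``sqrt((sd1^2 + sd2^2) / 2)``.
    Returns signed infinity when both SDs are zero but the means differ.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    diff = mean2 - mean1
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.copysign(np.inf, diff))
    return float(diff / pooled)


@dataclass(frozen=True)
class TTestResult:
    """Independent-samples t-test with its standardized effect size."""

    t: float
    df: float
    p: float
    cohens_d: float
    welch: bool = False


def independent_t(group1: Sequence[float], group2: Sequence[float],
                  welch: bool = False) -> TTestResult:
    """Two-sided independent t-test (pooled-variance Student's t by default,
    Welch behind the flag) with Cohen's d from the sample moments."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x1, ddof=1) == 0 and np.var(x2, ddof=1) == 0 \
            and np.mean(x1) != np.mean(x2):
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(x1, x2, equal_var=not welch)
    d = summary_cohens_d(float(np.mean(x1)), float(np.std(x1, ddof=1)), x1.size,
                         float(np.mean(x2)), float(np.std(x2, ddof=1)), x2.size)
    # sign convention: group2 - group1, like the d (scipy tests group1 - group2)
    return TTestResult(t=float(-res.statistic), df=float(res.df),
                       p=float(res.pvalue), cohens_d=d, welch=welch)


@dataclass(frozen=True)
class SexRatioTest:
    """Pearson chi-square on a 2x2 sex-by-cohort contingency table."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p: float
    df: int = 1


def sex_chi2(counts) -> SexRatioTest:
    """Pearson chi-square without continuity correction, df = 1."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("counts must be a nonnegative 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return SexRatioTest(counts=tuple(map(tuple, arr.astype(int))),
                        chi2=float(chi2), p=float(p), df=int(dof))


# --------------------------------------------------------------------------
# Stature-adjusted standardized regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Standardized OLS of one outcome on group, height and weight."""

    outcome: str
    r_squared: float
    f_pvalue: float
    coefficients: pd.DataFrame      # predictor, beta, ci_low, ci_high, p
    n: int
    condition_number: float
    collinear: bool

    def beta(self, predictor: str) -> float:
        row = self.coefficients.set_index("predictor").loc[predictor]
        return float(row["beta"])

    def p(self, predictor: str) -> float:
        row = self.coefficients.set_index("predictor").loc[predictor]
        return float(row["p"])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant predictor or outcome")
    return (x - np.mean(x)) / sd


def adjusted_regression(outcome: Sequence[float], group: Sequence[int],
                        heights: Sequence[float], weights: Sequence[float],
                        outcome_name: str = "outcome") -> RegressionResult:
    """OLS of the z-scored outcome on z-scored group (0/1), height and weight.

    Reports standardized betas with t-based 95% confidence intervals and
    per-coefficient p-values, the model R^2 and the overall F-test p-value.
    Predictor collinearity is flagged via the design-matrix condition number.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    h = np.asarray(heights, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = y.size
    if not (g.size == h.size == w.size == n):
        raise ValueError("outcome and predictors must have equal length")
    if n < 10:
        raise ValueError(f"need n >= 10 complete rows, got {n}")
    if np.any(~np.isfinite(np.column_stack([y, g, h, w]))):
        raise ValueError("missing values in used rows")
    Z = np.column_stack([_zscore(g), _zscore(h), _zscore(w)])
    X = sm.add_constant(Z)
    cond = float(np.linalg.cond(X))
    fit = sm.OLS(_zscore(y), X).fit()
    ci = fit.conf_int(alpha=0.05)
    names = ("group", "height", "weight")
    coefficients = pd.DataFrame({
        "predictor": names,
        "beta": [float(fit.params[i + 1]) for i in range(3)],
        "ci_low": [float(ci[i + 1, 0]) for i in range(3)],
        "ci_high": [float(ci[i + 1, 1]) for i in range(3)],
        "p": [float(fit.pvalues[i + 1]) for i in range(3)],
    })
    return RegressionResult(
        outcome=outcome_name,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        coefficients=coefficients,
        n=n,
        condition_number=cond,
        collinear=bool(cond > COLLINEARITY_CONDITION_LIMIT),
    )


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def build_report(descriptives: pd.DataFrame,
                 tests: Mapping[str, TTestResult],
                 regressions: Mapping[str, RegressionResult],
                 cohort_order: tuple[str, str],
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the two report tables.

    The descriptive/effect table has one row per parameter in report order:
    per cohort ``mean (SD)`` and CV, then the t-test p and Cohen's d.  The
    regression table carries the overall p/R^2 and, per predictor, the p,
    standardized beta and its 95% CI.  ``significant`` marks p < 0.05; no
    multiplicity correction is applied.  Empty inputs yield empty tables with
    headers.
    """
    c1, c2 = cohort_order
    desc = descriptives.set_index(["parameter", "cohort"]) if len(descriptives) \
        else pd.DataFrame()
    rows3, rows4 = [], []
    for name in PARAMETER_NAMES:
        if name not in tests and name not in regressions:
            continue
        row3 = {"parameter": name, "unit": PARAMETER_UNITS[name]}
        for label, cohort in (("1", c1), ("2", c2)):
            try:
                d = desc.loc[(name, cohort)]
                row3[f"mean_sd_{cohort}"] = f"{_fmt(d['mean'])} ({_fmt(d['sd'])})"
                row3[f"cv_{cohort}"] = _fmt(d["cv"])
            except (KeyError, AttributeError):
                row3[f"mean_sd_{cohort}"] = ""
                row3[f"cv_{cohort}"] = ""
        test = tests.get(name)
        if test is not None:
            row3["t_p"] = test.p
            row3["cohens_d"] = test.cohens_d
            row3["significant"] = bool(test.p < ALPHA)
        rows3.append(row3)

        reg = regressions.get(name)
        if reg is not None:
            row4 = {"parameter": name,
                    "overall_p": reg.f_pvalue, "r_squared": reg.r_squared,
                    "overall_significant": bool(reg.f_pvalue < ALPHA)}
            for _, c in reg.coefficients.iterrows():
                pred = c["predictor"]
                row4[f"{pred}_p"] = c["p"]
                row4[f"{pred}_beta"] = c["beta"]
                row4[f"{pred}_ci"] = f"({_fmt(c['ci_low'])}; {_fmt(c['ci_high'])})"
                row4[f"{pred}_significant"] = bool(c["p"] < ALPHA)
            rows4.append(row4)

    cols3 = (["parameter", "unit",
              f"mean_sd_{c1}", f"cv_{c1}", f"mean_sd_{c2}", f"cv_{c2}",
              "t_p", "cohens_d", "significant"])
    cols4 = (["parameter", "overall_p", "r_squared", "overall_significant"]
             + [f"{p}_{s}" for p in ("group", "height", "weight")
                for s in ("p", "beta", "ci", "significant")])
    table3 = pd.DataFrame(rows3, columns=cols3)
    table4 = pd.DataFrame(rows4, columns=cols4)
    return table3, table4
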