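"""Statistical stage: effect sizes, tests, matching, regression, reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from passmotion.stats import (
    MatchingError,
    adjusted_regression,
    build_report,
    describe,
    independent_t,
    match_cohorts,
    sex_chi2,
    summary_cohens_d,
)
from passmotion.skeleton import PARAMETER_NAMES, SubjectRecord

from conftest import SEED


# -- Cohen's d from summary moments ----------------------------------------

def test_summary_cohens_d_published_weight_row():
    d = summary_cohens_d(60.3, 9.4, 25, 68.8, 9.5, 25)
    assert d == pytest.approx(0.90, abs=0.01)


def test_summary_cohens_d_published_hand_deflection_row():
    d = summary_cohens_d(5.6, 2.43, 25, 10.2, 2.88, 25)
    assert d == pytest.approx(1.73, abs=0.01)   # printed 1.72; input rounding


def test_summary_cohens_d_equal_means_is_zero():
    assert summary_cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0


def test_summary_cohens_d_zero_sds_unequal_means_is_infinite():
    d = summary_cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)
    assert np.isinf(d) and d > 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    m1=st.floats(-50, 50), m2=st.floats(-50, 50),
    s1=st.floats(0.1, 20), s2=st.floats(0.1, 20),
    scale=st.floats(0.01, 100),
)
def test_summary_cohens_d_antisymmetric_and_scale_invariant(m1, m2, s1, s2, scale):
    d12 = summary_cohens_d(m1, s1, 25, m2, s2, 25)
    d21 = summary_cohens_d(m2, s2, 25, m1, s1, 25)
    assert d12 == pytest.approx(-d21, abs=1e-12)
    scaled = summary_cohens_d(m1 * scale, s1 * scale, 25, m2 * scale, s2 * scale, 25)
    assert scaled == pytest.approx(d12, rel=1e-9, abs=1e-9)


# -- independent t-test -----------------------------------------------------

def test_independent_t_identical_groups():
    x = [1.0, 2.0, 3.0, 4.0]
    res = independent_t(x, x)
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-12)
    assert res.cohens_d == 0.0
    assert res.df == 6


def test_independent_t_matches_moment_based_d_exactly(rng):
    x1 = rng.normal(0, 1, 25)
    x2 = rng.normal(0.5, 1.2, 25)
    res = independent_t(x1, x2)
    d = summary_cohens_d(x1.mean(), x1.std(ddof=1), 25,
                         x2.mean(), x2.std(ddof=1), 25)
    assert res.cohens_d == pytest.approx(d, abs=1e-14)
    # sign convention: positive d/t when group2 mean is larger
    assert np.sign(res.t) == np.sign(res.cohens_d)


def test_independent_t_zero_pooled_variance_is_an_error():
    with pytest.raises(ValueError, match="zero pooled variance"):
        independent_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


def test_independent_t_published_weight_moments_median_p(rng):
    """Replicated draws at the published weight moments put the median p near
    the printed .002 (within an order of magnitude)."""
    a = rng.normal(60.3, 9.4, (1000, 25))
    b = rng.normal(68.8, 9.5, (1000, 25))
    p = sps.ttest_ind(a, b, axis=1).pvalue
    assert 2e-4 <= np.median(p) <= 2e-2


def test_t_test_type_I_calibration_under_null():
    """With no true group effect, ~5% of parameters reject at alpha=.05."""
    from passmotion.simulate import cohort_spec_from_published, \
        simulate_parameter_cohort

    spec = cohort_spec_from_published("Japanese")
    rejections, total = 0, 0
    for ss in np.random.SeedSequence(SEED).spawn(400):
        r = np.random.default_rng(ss)
        _, t1 = simulate_parameter_cohort(spec, r)
        _, t2 = simulate_parameter_cohort(spec, r)
        p = sps.ttest_ind(t1.to_numpy(), t2.to_numpy(), axis=0).pvalue
        rejections += int((p < 0.05).sum())
        total += p.size
    rate = rejections / total
    # 3-sigma Monte-Carlo band around .05 (correlation-inflated margin)
    assert 0.05 - 0.012 <= rate <= 0.05 + 0.012


# -- chi-square -------------------------------------------------------------

def test_sex_chi2_published_counts():
    res = sex_chi2([[11, 12], [14, 13]])
    assert res.p == pytest.approx(0.776, abs=0.001)
    assert res.df == 1


def test_sex_chi2_identical_columns():
    res = sex_chi2([[10, 10], [15, 15]])
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-12)


def test_sex_chi2_matches_direct_formula(rng):
    for _ in range(20):
        table = rng.integers(1, 40, size=(2, 2)).astype(float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        direct = ((table - expected) ** 2 / expected).sum()
        assert sex_chi2(table).chi2 == pytest.approx(direct, abs=1e-9)


def test_sex_chi2_zero_marginal_is_an_error():
    with pytest.raises(ValueError, match="zero marginal"):
        sex_chi2([[0, 0], [5, 5]])


# -- descriptives -----------------------------------------------------------

def _with_moments(n, mean, sd, rng):
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def test_describe_cv_matches_published_asymmetry_row(rng):
    values = _with_moments(25, 6.73, 5.77, rng)
    table = pd.DataFrame({"sip_amplitude_asymmetry": values},
                         index=[f"s{i}" for i in range(25)])
    cohorts = pd.Series("Japanese", index=table.index)
    desc = describe(table, cohorts)
    row = desc.iloc[0]
    assert row["cv"] == pytest.approx(5.77 / 6.73, abs=1e-9)
    assert row["cv"] == pytest.approx(0.857, abs=0.001)
    assert row["n"] == 25


def test_describe_constant_column_and_negative_mean(rng):
    table = pd.DataFrame({
        "a": np.full(10, 3.0),
        "b": np.full(10, -1.0) + rng.normal(0, 0.1, 10),
    })
    cohorts = pd.Series("X", index=table.index)
    desc = describe(table, cohorts).set_index("parameter")
    assert desc.loc["a", "sd"] == 0.0 and desc.loc["a", "cv"] == 0.0
    assert np.isnan(desc.loc["b", "cv"])
    assert "undefined" in desc.loc["b", "flag"]


def test_describe_shapiro_null_calibration():
    """Shapiro-Wilk p-values are uniform for normal samples of n=25."""
    rng = np.random.default_rng(SEED)
    pvals = np.array([sps.shapiro(rng.standard_normal(25)).pvalue
                      for _ in range(1000)])
    frac = np.mean(pvals < 0.05)
    se = np.sqrt(0.05 * 0.95 / 1000)
    assert abs(frac - 0.05) <= 3 * se + 1e-9
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# -- matching ---------------------------------------------------------------

def _subject(i, sex, age, height, weight, cohort="pool"):
    return SubjectRecord(f"{cohort}_{i}", cohort, sex, age, height, weight)


def test_match_cohorts_reproduces_reference_sex_counts(rng):
    reference = ([_subject(i, "F", 30, 160, 55, "ref") for i in range(11)]
                 + [_subject(i + 11, "M", 30, 170, 65, "ref") for i in range(14)])
    pool = []
    for i in range(80):
        sex = "F" if i % 2 == 0 else "M"
        age = float(rng.uniform(19, 44))           # some fail the age filter
        height = float(rng.uniform(150, 195))
        bmi = float(rng.uniform(17.5, 30.5))       # some fail the BMI filter
        weight = bmi * (height / 100) ** 2
        pool.append(_subject(i, sex, age, height, min(weight, 150.0)))
    matched = match_cohorts(pool, reference)
    assert len(matched) == 25
    assert sum(s.sex == "F" for s in matched) == 11
    assert sum(s.sex == "M" for s in matched) == 14
    assert all(20 <= s.age <= 40 and 18 <= s.bmi <= 29 for s in matched)


def test_match_cohorts_empty_reference_is_an_error():
    with pytest.raises(MatchingError, match="empty"):
        match_cohorts([_subject(0, "F", 30, 160, 55)], [])


def test_match_cohorts_insufficient_stratum_names_the_sex():
    reference = [_subject(i, "M", 30, 175, 70, "ref") for i in range(3)]
    pool = [_subject(0, "F", 30, 160, 55)]
    with pytest.raises(MatchingError, match="stratum M"):
        match_cohorts(pool, reference)


def test_match_cohorts_bmi_tie_prefers_shorter_candidate():
    reference = [_subject(0, "M", 30, 170, 65, "ref")]
    tall = _subject(1, "M", 30, 190, 65 * (1.9 / 1.7) ** 2)
    short = _subject(2, "M", 30, 170, 65)
    assert tall.bmi == pytest.approx(short.bmi, abs=1e-9)
    matched = match_cohorts([tall, short], reference)
    assert matched[0].subject_id == short.subject_id


# -- adjusted regression ----------------------------------------------------

def _design(rng, n=50):
    group = np.repeat([0, 1], n // 2)
    heights = rng.normal(170, 9, n)
    weights = rng.normal(65, 9, n)
    return group, heights, weights


def test_regression_outcome_equal_to_height_copy(rng):
    group, heights, weights = _design(rng)
    z_h = (heights - heights.mean()) / heights.std(ddof=1)
    res = adjusted_regression(z_h, group, heights, weights)
    assert res.beta("height") == pytest.approx(1.0, abs=1e-8)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)
    assert abs(res.beta("group")) < 1e-8 and abs(res.beta("weight")) < 1e-8
    assert not res.collinear


def test_regression_r2_invariant_to_affine_predictor_rescaling(rng):
    group, heights, weights = _design(rng)
    y = rng.normal(0, 1, 50) + 0.03 * heights
    a = adjusted_regression(y, group, heights, weights)
    b = adjusted_regression(y, group, heights * 2.54 + 3.0, weights)
    assert b.r_squared == pytest.approx(a.r_squared, abs=1e-12)
    assert b.beta("height") == pytest.approx(a.beta("height"), abs=1e-10)


def test_regression_collinear_predictors_flagged(rng):
    group = np.repeat([0, 1], 25)
    heights = rng.normal(170, 9, 50)
    weights = 2.0 * heights - 100.0               # exactly collinear
    res = adjusted_regression(rng.normal(0, 1, 50), group, heights, weights)
    assert res.collinear


def test_regression_input_validation(rng):
    with pytest.raises(ValueError, match="n >= 10"):
        adjusted_regression([1, 2, 3], [0, 1, 0], [170, 171, 172], [60, 61, 62])
    group, heights, weights = _design(rng)
    y = rng.normal(0, 1, 50)
    y[3] = np.nan
    with pytest.raises(ValueError, match="missing values"):
        adjusted_regression(y, group, heights, weights)


# -- report builder ---------------------------------------------------------

def test_build_report_empty_inputs_give_empty_tables_with_headers():
    t3, t4 = build_report(pd.DataFrame(), {}, {}, ("Japanese", "German"))
    assert len(t3) == 0 and len(t4) == 0
    assert "mean_sd_Japanese" in t3.columns
    assert "group_beta" in t4.columns


def test_build_report_orders_and_marks_significance(rng):
    from passmotion.pipeline import PipelineConfig, simulate_cohort_parameters, \
        analyze_parameters

    cfg = PipelineConfig(seed=SEED, mode="parameter", n_per_cohort=25)
    subjects, wide, cohorts = simulate_cohort_parameters(cfg)
    desc, tests, regs, _ = analyze_parameters(wide, cohorts, subjects, cfg)
    t3, t4 = build_report(desc, tests, regs, ("Japanese", "German"))
    assert list(t3["parameter"]) == list(PARAMETER_NAMES)
    assert len(t3) == 23 and len(t4) == 23
    for _, row in t3.iterrows():
        assert row["significant"] == (row["t_p"] < 0.05)
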