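"""Generator contracts: determinism, closed forms, cohort calibration."""

import dataclasses

import numpy as np
import pytest

from passmotion.extract import (
    detect_transitions,
    extract_poco,
    extract_scsw,
    extract_sip,
    extract_slw,
)
from passmotion.simulate import (
    SasParams,
    SipParams,
    SwayParams,
    TruncNormSpec,
    WalkParams,
    cohort_spec_from_published,
    ground_truth_from_targets,
    simulate_parameter_cohort,
    simulate_poco,
    simulate_sas,
    simulate_sip,
    simulate_subject_recordings,
    simulate_walk,
    smoothstep_window_fraction,
)

from conftest import SEED


# -- parameter containers ---------------------------------------------------

def test_walk_speed_identity_holds_by_construction():
    wp = WalkParams(cadence_spm=110.0, step_length_m=0.69)
    assert wp.speed_m_s == pytest.approx(110.0 * 0.69 / 60.0, abs=1e-12)
    with pytest.raises(ValueError, match="cadence"):
        WalkParams(cadence_spm=30.0, step_length_m=0.69)


def test_sway_params_reject_negative_radius():
    with pytest.raises(ValueError, match="radius"):
        SwayParams(radius_deg=-0.1, rate_hz=0.2)


# -- determinism ------------------------------------------------------------

def test_identical_seeds_give_bit_identical_recordings(clean_gt):
    a = simulate_sip(clean_gt, seed=SEED)
    b = simulate_sip(clean_gt, seed=SEED)
    assert np.array_equal(a.sequence.positions, b.sequence.positions)
    assert np.array_equal(a.sequence.timestamps, b.sequence.timestamps)
    c = simulate_sip(clean_gt, seed=SEED + 1)
    gt_noisy = dataclasses.replace(clean_gt, noise_sd_m=0.001)
    a2 = simulate_sip(gt_noisy, seed=SEED)
    b2 = simulate_sip(gt_noisy, seed=SEED)
    c2 = simulate_sip(gt_noisy, seed=SEED + 1)
    assert np.array_equal(a2.sequence.positions, b2.sequence.positions)
    assert not np.array_equal(a2.sequence.positions, c2.sequence.positions)


def test_subject_recording_set_composition_and_determinism(clean_gt):
    recs = simulate_subject_recordings(clean_gt, seed=SEED)
    assert len(recs) == 14
    by_task = {}
    for r in recs:
        by_task.setdefault(r.task, []).append(r.repetition)
    assert {t: sorted(v) for t, v in by_task.items()} == {
        "POCO": [1], "SCSW": [1, 2, 3], "SMSW": [1, 2, 3],
        "SLW": [1, 2, 3], "SAS": [1, 2, 3], "SIP": [1]}
    again = simulate_subject_recordings(clean_gt, seed=SEED)
    for a, b in zip(recs, again):
        assert np.array_equal(a.sequence.positions, b.sequence.positions)


def test_repetition_jitter_changes_averages(clean_gt):
    plain = simulate_subject_recordings(clean_gt, seed=SEED)
    jittered = simulate_subject_recordings(clean_gt, seed=SEED,
                                           repetition_jitter=0.05)
    scsw_plain = extract_scsw([r for r in plain if r.task == "SCSW"])
    scsw_jit = extract_scsw([r for r in jittered if r.task == "SCSW"])
    assert scsw_jit["scsw_cadence"] != pytest.approx(
        scsw_plain["scsw_cadence"], abs=1e-6)
    # identical repetitions average to the single-recording value
    single = extract_scsw([plain[1]] * 3)
    assert single["scsw_cadence"] == pytest.approx(scsw_plain["scsw_cadence"],
                                                   rel=1e-9)


# -- POCO closed forms ------------------------------------------------------

def test_poco_zero_radius_zero_jitter_gives_zero_sway(clean_gt):
    still = dataclasses.replace(
        clean_gt,
        poco_open=SwayParams(0.0, 0.0), poco_closed=SwayParams(0.0, 0.0))
    res = extract_poco(simulate_poco(still, seed=SEED))
    assert res["poco_sway_speed_open"] == pytest.approx(0.0, abs=1e-9)
    assert res["poco_deflection_range_open"] == pytest.approx(0.0, abs=1e-9)
    assert hasattr(res["poco_romberg_range"], "reason")     # flagged missing


def test_poco_circle_closed_form_vs_dense_numerical_oracle(circle_gt):
    """Mean angular speed 2*pi*f*r and range 2r, cross-checked against a
    densely sampled numerical path-length computation of the same circle."""
    res = extract_poco(simulate_poco(circle_gt, seed=SEED))
    r, f = 0.5, 0.25
    # dense numerical oracle: angular path length per second of the circle
    tt = np.linspace(0.0, 20.0, 200001)
    theta = np.column_stack([r * np.cos(2 * np.pi * f * tt),
                             r * np.sin(2 * np.pi * f * tt)])
    oracle_speed = np.sum(np.linalg.norm(np.diff(theta, axis=0), axis=1)) / 20.0
    assert oracle_speed == pytest.approx(2 * np.pi * f * r, rel=1e-6)
    assert res["poco_sway_speed_open"] == pytest.approx(oracle_speed, rel=0.02)
    assert res["poco_deflection_range_open"] == pytest.approx(2 * r, rel=0.02)
    assert res["poco_romberg_range"] == pytest.approx(1.0, rel=0.02)
    assert res["poco_romberg_speed"] == pytest.approx(1.0, rel=0.02)


def test_poco_defaults_recover_published_means_within_10pct(clean_gt):
    res = extract_poco(simulate_poco(clean_gt, seed=SEED))
    assert res["poco_deflection_range_open"] == pytest.approx(1.01, rel=0.10)
    assert res["poco_sway_speed_open"] == pytest.approx(0.22, rel=0.10)
    assert res["poco_deflection_range_closed"] == pytest.approx(1.10, rel=0.10)
    assert res["poco_sway_speed_closed"] == pytest.approx(0.31, rel=0.10)


def test_poco_recovery_robust_to_1mm_landmark_jitter(clean_gt):
    """With 1 mm isotropic jitter the sway-band filtering keeps recovery
    close; the deflection range (a max statistic) carries an upward noise
    bias, so the bound is wider than the jitter-free one."""
    noisy = dataclasses.replace(clean_gt, noise_sd_m=0.001)
    res = extract_poco(simulate_poco(noisy, seed=SEED))
    assert res["poco_sway_speed_open"] == pytest.approx(0.22, rel=0.20)
    assert res["poco_sway_speed_closed"] == pytest.approx(0.31, rel=0.20)
    assert res["poco_deflection_range_open"] == pytest.approx(1.01, rel=0.20)
    assert res["poco_deflection_range_closed"] == pytest.approx(1.10, rel=0.20)


# -- walks ------------------------------------------------------------------

def test_walk_recovers_cadence_step_length_speed(clean_gt):
    gt = dataclasses.replace(
        clean_gt, scsw=WalkParams(cadence_spm=110.0, step_length_m=0.69))
    recs = [simulate_walk(gt, "SCSW", seed=s) for s in (1, 2, 3)]
    res = extract_scsw(recs)
    assert res["scsw_gait_speed"] == pytest.approx(110 * 0.69 / 60, rel=0.05)
    assert res["scsw_cadence"] == pytest.approx(110.0, abs=2.0)
    assert res["scsw_step_length"] == pytest.approx(69.0, abs=3.0)


def test_line_walk_zero_amplitudes_give_zero_variability(clean_gt):
    gt = dataclasses.replace(clean_gt, slw_trunk_lean_deg=0.0,
                             slw_arm_swing_deg=0.0)
    res = extract_slw([simulate_walk(gt, "SLW", seed=s) for s in (1, 2, 3)])
    assert res["slw_trunk_sway_variability"] == pytest.approx(0.0, abs=1e-6)
    assert res["slw_arm_movement_variability"] == pytest.approx(0.0, abs=1e-6)


def test_line_walk_sinusoid_sd_closed_form(clean_gt):
    gt = dataclasses.replace(clean_gt, slw_trunk_lean_deg=2.0)
    res = extract_slw([simulate_walk(gt, "SLW", seed=s) for s in (1, 2, 3)])
    assert res["slw_trunk_sway_variability"] == pytest.approx(2 / np.sqrt(2),
                                                              rel=0.03)


# -- SAS --------------------------------------------------------------------

def test_sas_linear_ramp_gives_090_of_profile_duration(clean_gt):
    sas = SasParams(stand_up_duration_s=1.0, sit_down_duration_s=1.0,
                    trunk_up_m=0.14, hand_up_m=0.07,
                    trunk_down_m=0.12, hand_down_m=0.06, profile="linear")
    gt = dataclasses.replace(clean_gt, sas=sas)
    up, down = detect_transitions(simulate_sas(gt, seed=SEED))
    assert up.duration == pytest.approx(0.90, abs=0.05)
    assert down.duration == pytest.approx(0.90, abs=0.05)


def test_smoothstep_window_fraction_against_dense_oracle():
    """The 5%/95% crossing fraction of the smoothstep profile, validated by
    dense sampling of the analytic curve."""
    u = np.linspace(0.0, 1.0, 2_000_001)
    s = u * u * (3 - 2 * u)
    u1 = u[np.searchsorted(s, 0.05)]
    u2 = u[np.searchsorted(s, 0.95)]
    assert smoothstep_window_fraction() == pytest.approx(u2 - u1, abs=1e-5)


def test_sas_zero_hand_excursion_gives_zero_deflection(clean_gt):
    sas = dataclasses.replace(clean_gt.sas, hand_up_m=0.0, hand_down_m=0.0)
    gt = dataclasses.replace(clean_gt, sas=sas)
    from passmotion.extract import extract_sas
    res = extract_sas([simulate_sas(gt, seed=s) for s in (1, 2, 3)])
    assert res["sas_stand_up_hand_deflection"] == pytest.approx(0.0, abs=1e-6)
    assert res["sas_sitting_down_hand_deflection"] == pytest.approx(0.0, abs=1e-6)


# -- SIP --------------------------------------------------------------------

def test_sip_regular_equal_steps_closed_form(clean_gt):
    sip = SipParams(amplitude_left_m=0.24, amplitude_right_m=0.24,
                    interval_mean_s=1 / 1.8, interval_cv=0.0)
    res = extract_sip(simulate_sip(dataclasses.replace(clean_gt, sip=sip),
                                   seed=SEED))
    assert res["sip_cadence"] == pytest.approx(108.0, abs=2.0)
    assert res["sip_knee_amplitude"] == pytest.approx(24.0, abs=1.0)
    assert res["sip_amplitude_asymmetry"] == pytest.approx(0.0, abs=1.0)
    assert res["sip_arrhythmicity"] == pytest.approx(0.0, abs=1.0)


def test_sip_unequal_amplitudes_give_asymmetry_formula(clean_gt):
    sip = SipParams(amplitude_left_m=0.20, amplitude_right_m=0.25,
                    interval_mean_s=0.55, interval_cv=0.0)
    res = extract_sip(simulate_sip(dataclasses.replace(clean_gt, sip=sip),
                                   seed=SEED))
    assert res["sip_amplitude_asymmetry"] == pytest.approx(20.0, abs=3.0)


def test_sip_interval_cv_sets_arrhythmicity(clean_gt):
    sip = dataclasses.replace(clean_gt.sip, interval_cv=0.09)
    res = extract_sip(simulate_sip(dataclasses.replace(clean_gt, sip=sip),
                                   seed=SEED))
    assert res["sip_arrhythmicity"] == pytest.approx(9.0, abs=2.0)


# -- parameter-level cohorts ------------------------------------------------

def test_parameter_cohort_stature_margins(rng):
    spec = cohort_spec_from_published("Japanese")
    subjects, table = simulate_parameter_cohort(spec, rng)
    heights = np.array([s.height_cm for s in subjects])
    assert len(subjects) == 25
    assert sum(s.sex == "F" for s in subjects) == 11
    assert abs(heights.mean() - 166.8) < 3 * 8.8 / np.sqrt(25)
    assert heights.min() >= 153.0 and heights.max() <= 185.0
    assert table.shape == (25, 23)


def test_parameter_cohort_zero_sd_gives_constant_column(rng):
    spec = cohort_spec_from_published("Japanese")
    params = dict(spec.parameters)
    params["sip_cadence"] = (108.8, 0.0)
    spec = dataclasses.replace(spec, parameters=params, height_beta={})
    _, table = simulate_parameter_cohort(spec, rng)
    assert np.allclose(table["sip_cadence"], 108.8)


def test_parameter_cohort_height_link_preserves_marginals():
    """Height-linked generation keeps the marginal mean/SD of the parameter."""
    spec = cohort_spec_from_published("Japanese", n=4000)
    _, table = simulate_parameter_cohort(spec, seed=SEED)
    mean, sd = spec.parameters["scsw_step_length"]
    col = table["scsw_step_length"]
    assert col.mean() == pytest.approx(mean, abs=4 * sd / np.sqrt(4000))
    assert col.std(ddof=1) == pytest.approx(sd, rel=0.05)
    # and the built-in height coefficient induces the expected correlation
    subjects, table2 = simulate_parameter_cohort(spec, seed=SEED)
    h = np.array([s.height_cm for s in subjects])
    r = np.corrcoef(h, table2["scsw_step_length"])[0, 1]
    assert r == pytest.approx(spec.height_beta["scsw_step_length"], abs=0.06)


def test_truncnorm_spec_rejects_bad_bounds():
    with pytest.raises(ValueError, match="infeasible truncation"):
        TruncNormSpec(170.0, 5.0, 180.0, 160.0)


# -- time-scaling covariance ------------------------------------------------

def test_time_scaling_covariance(clean_gt):
    """Stretching time by c scales transition times by c and divides cadence
    by c; displacement amplitudes are unchanged."""
    from passmotion.skeleton import TaskRecording

    c = 1.25
    sas = simulate_sas(clean_gt, seed=SEED)
    scaled = TaskRecording("SAS", 1, tuple(t * c for t in sas.cue_times),
                           sas.sequence.time_scaled(c))
    up0, _ = detect_transitions(sas)
    up1, _ = detect_transitions(scaled)
    assert up1.duration == pytest.approx(c * up0.duration, rel=0.02)

    sip = simulate_sip(clean_gt, seed=SEED)
    sip_scaled = TaskRecording("SIP", 1, (), sip.sequence.time_scaled(c))
    res0 = extract_sip(sip)
    res1 = extract_sip(sip_scaled)
    assert res1["sip_cadence"] == pytest.approx(res0["sip_cadence"] / c, rel=0.02)
    assert res1["sip_knee_amplitude"] == pytest.approx(res0["sip_knee_amplitude"],
                                                       rel=0.02)
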