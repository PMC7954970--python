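"""End-to-end orchestration: simulate -> extract -> analyze -> report.

A single :class:`PipelineConfig` (YAML-loadable) fixes every setting and one
global seed; the seed is expanded into per-cohort and per-subject child
streams through ``numpy.random.SeedSequence`` spawn keys, so the whole run is
reproducible bit-for-bit and the per-subject streams are independent.

Two simulation modes:

* ``kinematic`` — per subject, draw 23 parameter targets from the cohort
  distributions, invert them into generating values, simulate the 14 task
  recordings, and run the full extractor stack on them;
* ``parameter`` — use the drawn parameter table directly (fast path for
  purely statistical studies of the comparison stage).

:func:`verify_printed_effects` is the self-check against the published
summary statistics: every Cohen's d and CV derivable from the published
group means/SDs is recomputed and compared, propagating the half-ULP
rounding interval of each printed input cell.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import published
from .extract import extract_all
from .simulate import (
    CohortSpec,
    cohort_spec_from_published,
    ground_truth_from_targets,
    simulate_parameter_cohort,
    simulate_subject_recordings,
)
from .skeleton import (
    PARAMETER_NAMES,
    ParameterVector,
    SubjectRecord,
    parameter_table_to_tidy,
    write_skeleton_csv,
    write_subjects_csv,
)
from .stats import (
    ALPHA,
    adjusted_regression,
    build_report,
    describe,
    independent_t,
    match_cohorts,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "verify_printed_effects",
]

logger = logging.getLogger("passmotion")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    seed: int = 0
    mode: str = "kinematic"              # "kinematic" | "parameter"
    cohorts: tuple[CohortSpec, ...] = ()
    n_per_cohort: int | None = None
    noise_sd_m: float = 0.001
    repetition_jitter: float = 0.02
    alpha: float = ALPHA
    welch: bool = False
    write_recordings: bool = False

    def __post_init__(self):
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a nonnegative integer")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("kinematic", "parameter"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.cohorts) == 0:
            object.__setattr__(self, "cohorts", tuple(
                cohort_spec_from_published(label, self.n_per_cohort)
                for label in published.COHORT_LABELS))
        if len(self.cohorts) != 2:
            raise ValueError("pipeline compares exactly 2 cohorts")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        n = d.get("n_per_cohort")
        cohorts = []
        for entry in d.pop("cohorts", []):
            if isinstance(entry, str):
                cohorts.append(cohort_spec_from_published(entry, n))
            else:
                cohorts.append(CohortSpec.from_dict(entry))
        return cls(cohorts=tuple(cohorts),
                   **{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}
                      and k != "cohorts"})

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# Simulation + extraction stages
# --------------------------------------------------------------------------

def simulate_cohort_parameters(config: PipelineConfig):
    """Stage 1: subjects and per-subject parameter values for both cohorts.

    Returns (subjects, wide_table) where ``wide_table`` is indexed by subject
    id with the 23 parameter columns, plus a ``cohort`` series.
    """
    root = np.random.SeedSequence(config.seed)
    cohort_seeds = root.spawn(len(config.cohorts))
    all_subjects: list[SubjectRecord] = []
    tables = []
    for spec, cseed in zip(config.cohorts, cohort_seeds):
        try:
            subjects, targets = simulate_parameter_cohort(
                spec, np.random.default_rng(cseed))
        except ValueError as exc:
            raise PipelineError(f"simulate stage, cohort {spec.name!r}: {exc}") from exc
        if config.mode == "parameter":
            table = targets
        else:
            table = _kinematic_cohort(config, spec, subjects, targets, cseed)
        all_subjects.extend(subjects)
        tables.append(table)
    recordings = {}
    for table in tables:
        recordings.update(table.attrs.get("recordings", {}))
    wide = pd.concat(tables)
    wide.attrs["recordings"] = recordings          # pd.concat drops attrs
    cohorts = pd.Series({s.subject_id: s.cohort for s in all_subjects},
                        name="cohort")
    return all_subjects, wide, cohorts


def _kinematic_cohort(config, spec, subjects, targets, cohort_seed):
    """Simulate full recordings per subject and extract their parameters."""
    subject_seeds = cohort_seed.spawn(len(subjects))
    rows = {}
    recordings_store = {}
    for subject, target_row, sseed in zip(subjects, targets.itertuples(index=False),
                                          subject_seeds):
        try:
            gt = ground_truth_from_targets(
                dict(zip(targets.columns, target_row)),
                height_m=subject.height_cm / 100.0,
                noise_sd_m=config.noise_sd_m)
            recs = simulate_subject_recordings(
                gt, sseed, repetition_jitter=config.repetition_jitter)
            pv = extract_all(recs)
        except Exception as exc:
            raise PipelineError(
                f"simulate/extract stage, cohort {spec.name!r}, "
                f"subject {subject.subject_id!r}: {exc}") from exc
        rows[subject.subject_id] = pv.as_series()
        recordings_store[subject.subject_id] = recs
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    table.attrs["recordings"] = recordings_store if config.write_recordings else {}
    return table


def analyze_parameters(wide: pd.DataFrame, cohorts: pd.Series,
                       subjects: Sequence[SubjectRecord],
                       config: PipelineConfig):
    """Stage 3: descriptives, t-tests + d, and adjusted regressions."""
    c1, c2 = (spec.name for spec in config.cohorts)
    stature = pd.DataFrame({
        "height": {s.subject_id: s.height_cm for s in subjects},
        "weight": {s.subject_id: s.weight_kg for s in subjects},
    }).reindex(wide.index)
    group = cohorts.reindex(wide.index).map({c1: 0, c2: 1})

    descriptives = describe(wide, cohorts)
    tests, regressions, notes = {}, {}, {}
    for name in PARAMETER_NAMES:
        if name not in wide.columns:
            continue
        x1 = wide.loc[group == 0, name].dropna()
        x2 = wide.loc[group == 1, name].dropna()
        try:
            tests[name] = independent_t(x1, x2, welch=config.welch)
        except ValueError as exc:
            notes[name] = f"t-test skipped: {exc}"
        rows = pd.concat([wide[name], group, stature], axis=1).dropna()
        try:
            regressions[name] = adjusted_regression(
                rows[name], rows["cohort"], rows["height"], rows["weight"],
                outcome_name=name)
        except ValueError as exc:
            notes[name] = notes.get(name, "") + f" regression skipped: {exc}"
    return descriptives, tests, regressions, notes


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> dict:
    """Run simulate -> extract -> analyze -> report and write the bundle.

    Writes ``subjects.csv``, ``parameters.csv`` (tidy), ``table3.tsv``,
    ``table4.tsv``, ``results.json`` and ``run_log.json`` under ``out_dir``
    (skeleton CSVs per recording too when ``write_recordings`` is set).
    Identical config and seed give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: mode=%s seed=%d", config.mode, config.seed)

    subjects, wide, cohorts = simulate_cohort_parameters(config)
    c1, c2 = (spec.name for spec in config.cohorts)

    write_subjects_csv(subjects, out / "subjects.csv")
    tidy = parameter_table_to_tidy(wide)
    tidy.to_csv(out / "parameters.csv", index=False)

    if config.write_recordings and config.mode == "kinematic":
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for table in (wide,):
            for sid, recs in table.attrs.get("recordings", {}).items():
                for rec in recs:
                    write_skeleton_csv(
                        rec, rec_dir / f"{sid}_{rec.task}_{rec.repetition}.csv")

    try:
        descriptives, tests, regressions, notes = analyze_parameters(
            wide, cohorts, subjects, config)
        table3, table4 = build_report(descriptives, tests, regressions, (c1, c2))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"analyze stage: {exc}") from exc

    table3.to_csv(out / "table3.tsv", sep="\t", index=False)
    table4.to_csv(out / "table4.tsv", sep="\t", index=False)

    results = {
        "metadata": {
            "seed": int(config.seed),
            "mode": config.mode,
            "cohorts": [c1, c2],
            "group_coding": {c1: 0, c2: 1},
            "effect_sign": f"{c2} minus {c1}",
            "alpha": config.alpha,
            "t_test": "welch" if config.welch else "student_pooled",
            "ci_method": "t-distribution on the standardized fit, 95%",
        },
        "descriptives": descriptives.to_dict(orient="records"),
        "t_tests": {k: {"t": v.t, "df": v.df, "p": v.p, "cohens_d": v.cohens_d}
                    for k, v in tests.items()},
        "regressions": {k: {
            "r_squared": v.r_squared, "f_pvalue": v.f_pvalue, "n": v.n,
            "condition_number": v.condition_number, "collinear": v.collinear,
            "coefficients": v.coefficients.to_dict(orient="records"),
        } for k, v in regressions.items()},
        "notes": notes,
    }
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, allow_nan=True)

    run_log = {
        "config": {
            "seed": int(config.seed), "mode": config.mode,
            "n_per_cohort": [spec.n for spec in config.cohorts],
            "noise_sd_m": config.noise_sd_m,
            "repetition_jitter": config.repetition_jitter,
            "alpha": config.alpha, "welch": config.welch,
        },
        "settings": {
            "resample_fs_hz": 30.0, "filter_cutoff_hz": 6.0, "filter_order": 4,
            "sway_cutoff_hz": 1.0, "poco_phase_guard_s": 0.5,
            "step_prominence_fraction": 0.25, "step_min_gap_s": 0.25,
            "speed_fit_margin_m": 0.5, "transition_thresholds": [0.05, 0.95],
            "min_transition_height_m": 0.10,
            "romberg_direction": "closed/open",
            "asymmetry": "|A_L - A_R| / max(A_L, A_R) * 100",
            "arrhythmicity": "100 * CV of merged inter-step intervals",
            "hand_deflection": "larger of the two hands",
            "seed_scheme": "SeedSequence(seed) -> cohort children -> subject "
                           "children -> 14 (task, repetition) children",
        },
        "group_coding": {c1: 0, c2: 1},
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    logger.info("pipeline done: %d subjects, %d parameters tested",
                len(subjects), len(tests))
    return results


def match_stage(candidates: Sequence[SubjectRecord],
                reference: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    """Matching wrapped with pipeline error context."""
    try:
        return match_cohorts(candidates, reference)
    except ValueError as exc:
        raise PipelineError(f"matching stage: {exc}") from exc


# --------------------------------------------------------------------------
# Verification against the published summary statistics
# --------------------------------------------------------------------------

def _corner_interval(func, cells: Sequence[str]) -> tuple[float, float]:
    """Range of ``func`` over the half-ULP box around the printed cells."""
    halves = [published.half_ulp(c) for c in cells]
    centers = [float(c) for c in cells]
    lo, hi = np.inf, -np.inf
    for signs in itertools.product((-1.0, 1.0), repeat=len(cells)):
        v = func(*[c + s * h for c, s, h in zip(centers, signs, halves)])
        lo, hi = min(lo, v), max(hi, v)
    return lo, hi


def _pooled_d(m1, s1, m2, s2, n=published.N_PER_COHORT):
    from .stats import summary_cohens_d
    return summary_cohens_d(m1, max(s1, 0.0), n, m2, max(s2, 0.0), n)


def verify_printed_effects(d_tolerance: float = 0.02,
                           cv_tolerance: float = 0.005,
                           rows: Sequence[published.PublishedRow] | None = None,
                           ) -> pd.DataFrame:
    """Recompute every published Cohen's d and CV from the printed group
    means/SDs (N = 25 per cohort) and compare with the printed values.

    The printed inputs are rounded to their last printed decimal, so each
    recomputed quantity is an interval, not a point: a check passes when the
    printed value lies within the interval implied by half-ULP perturbations
    of its inputs, expanded by the stated tolerance (plus the printed value's
    own half-ULP for CV cells, which are sometimes printed at one decimal).
    Returns one pass/fail row per check.
    """
    if rows is None:
        rows = published.CHARACTERISTIC_ROWS + published.PARAMETER_ROWS
    out = []
    for row in rows:
        m1, s1, m2, s2 = row.floats()
        printed_d = float(row.d)
        lo, hi = _corner_interval(
            lambda a, b, c, e: _pooled_d(a, b, c, e),
            (row.mean1, row.sd1, row.mean2, row.sd2))
        recomputed = _pooled_d(m1, s1, m2, s2)
        dist = max(lo - printed_d, printed_d - hi, 0.0)
        out.append({
            "check": "cohens_d", "name": row.name, "cohort": "",
            "recomputed": recomputed, "printed": printed_d,
            "interval_low": lo, "interval_high": hi,
            "tolerance": d_tolerance, "passed": bool(dist <= d_tolerance),
        })
        for cohort, mean_s, sd_s, cv_s in (
                ("Japanese", row.mean1, row.sd1, row.cv1),
                ("German", row.mean2, row.sd2, row.cv2)):
            if cv_s is None:
                continue
            printed_cv = float(cv_s)
            lo, hi = _corner_interval(lambda m, s: s / m, (mean_s, sd_s))
            recomputed = float(sd_s) / float(mean_s)
            slack = cv_tolerance + published.half_ulp(cv_s)
            dist = max(lo - printed_cv, printed_cv - hi, 0.0)
            out.append({
                "check": "cv", "name": row.name, "cohort": cohort,
                "recomputed": recomputed, "printed": printed_cv,
                "interval_low": lo, "interval_high": hi,
                "tolerance": slack, "passed": bool(dist <= slack),
            })
    return pd.DataFrame(out)
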