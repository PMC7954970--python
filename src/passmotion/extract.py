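"""Extraction of the 23 spatiotemporal parameters from task recordings.

Every extractor operates on a preprocessed sequence (uniform 30 Hz resampling
followed by zero-phase 6 Hz low-pass filtering) and measures only relative
quantities, so all outputs are invariant to rigid horizontal translation of
the scene and to a constant shift of the time axis.

Definitions that the source protocol leaves open are isolated behind single
functions so they can be swapped: the step-amplitude asymmetry index
(:func:`amplitude_asymmetry`), the inter-step-interval arrhythmicity
(:func:`arrhythmicity`), and the 5%/95% amplitude-fraction transition timing
rule in :func:`detect_transitions`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.spatial.distance import pdist

from .skeleton import (
    LANDMARK_SET,
    PARAMETER_NAMES,
    TASK_PARAMETERS,
    ParameterVector,
    SkeletonSequence,
    TaskRecording,
)

__all__ = [
    "ExtractionError",
    "StepEvents",
    "TransitionWindow",
    "preprocess",
    "extract_poco",
    "detect_steps",
    "extract_scsw",
    "extract_smsw",
    "extract_slw",
    "detect_transitions",
    "extract_sas",
    "extract_sip",
    "extract_all",
    "amplitude_asymmetry",
    "arrhythmicity",
]

#: Resampling rate (Hz) and zero-phase low-pass cutoff (Hz) for preprocessing.
RESAMPLE_FS = 30.0
FILTER_CUTOFF_HZ = 6.0
FILTER_ORDER = 4

#: Step detection: peak prominence as a fraction of the signal SD, and the
#: minimum inter-event gap per side (seconds).
STEP_PROMINENCE_FRACTION = 0.25
STEP_MIN_GAP_S = 0.25

#: Gait-speed fit excludes this margin (m) at each end of the walk path.
SPEED_FIT_MARGIN_M = 0.5

#: Dedicated low-pass cutoff (Hz) for the sway-angle trajectory: quiet-stance
#: sway is dominated by sub-1 Hz content, while the angular path length (sway
#: speed) amplifies frame-to-frame tracking jitter without this.
SWAY_CUTOFF_HZ = 1.0

#: Guard band (s) trimmed on each side of the stance cue: the eyes-closing
#: instant carries a movement artifact and low-pass smear from the phase
#: change, which would otherwise bleed into both phases.
POCO_PHASE_GUARD_S = 0.5

#: Transition detection thresholds as fractions of the seated-to-standing
#: height difference, and the minimum credible height difference (m).
TRANSITION_THRESHOLDS = (0.05, 0.95)
MIN_TRANSITION_HEIGHT_M = 0.10


class ExtractionError(ValueError):
    """A recording does not support the requested parameter extraction."""


class _Missing:
    """Sentinel carrying the reason a single parameter could not be computed."""

    def __init__(self, reason: str):
        self.reason = reason


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def preprocess(seq: SkeletonSequence, fs: float = RESAMPLE_FS,
               cutoff_hz: float = FILTER_CUTOFF_HZ) -> SkeletonSequence:
    """Resample to a uniform grid and zero-phase low-pass filter.

    Kinect skeleton streams are jittery in time; linear resampling to exactly
    ``fs`` followed by a forward-backward Butterworth filter (order 4, cutoff
    ``cutoff_hz``) gives a fixed-rate, phase-preserving signal.  The input
    sequence is left untouched.
    """
    if seq.duration < 1.0:
        raise ExtractionError(f"sequence shorter than 1 s ({seq.duration:.3f} s)")
    t0 = float(seq.timestamps[0])
    n_out = int(np.floor(seq.duration * fs)) + 1
    grid = t0 + np.arange(n_out) / fs
    flat = seq.positions.reshape(seq.n_frames, -1)
    resampled = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        resampled[:, j] = np.interp(grid, seq.timestamps, flat[:, j])
    b, a = butter(FILTER_ORDER, cutoff_hz / (fs / 2.0))
    padlen = min(3 * max(len(a), len(b)), n_out - 1)
    smoothed = filtfilt(b, a, resampled, axis=0, padlen=padlen)
    return SkeletonSequence(grid, smoothed.reshape(n_out, -1, 3),
                            validate_rate=False)


def _phase_slice(t: np.ndarray, start: float, stop: float) -> np.ndarray:
    return (t >= start - 1e-12) & (t <= stop + 1e-12)


# --------------------------------------------------------------------------
# POCO — posturography
# --------------------------------------------------------------------------

def _sway_phase(pre: SkeletonSequence, start: float, stop: float) -> tuple[float, float]:
    """(deflection range deg, mean angular speed deg/s) for one stance phase.

    The sway angle is the two-component (ML, AP) angular displacement of the
    spine base about the ankle midpoint fixed at phase start: component-wise
    arctangent of the horizontal displacement from the phase-mean position
    over the spine-base height above the ankles.  Sway speed is the angular
    path length per second; the deflection range is the diameter of the
    angular trajectory.
    """
    if stop - start < 2.0:
        raise ExtractionError(f"stance phase shorter than 2 s ({stop - start:.2f} s)")
    t = pre.timestamps
    mask = _phase_slice(t, start, stop)
    base = pre.landmark("spine_base")[mask]
    first = int(np.argmax(mask))
    ankles = (pre.landmark("left_ankle")[first] + pre.landmark("right_ankle")[first]) / 2.0
    h = float(np.mean(base[:, 1]) - ankles[1])
    if h <= 0:
        raise ExtractionError("spine base below ankle level")
    horiz = base[:, [0, 2]] - base[:, [0, 2]].mean(axis=0)
    theta = np.rad2deg(np.arctan(horiz / h))          # (n, 2): ML, AP angles
    fs = 1.0 / pre.mean_dt
    b, a = butter(FILTER_ORDER, SWAY_CUTOFF_HZ / (fs / 2.0))
    theta = filtfilt(b, a, theta, axis=0,
                     padlen=min(3 * max(len(a), len(b)), theta.shape[0] - 1))
    path = float(np.sum(np.linalg.norm(np.diff(theta, axis=0), axis=1)))
    speed = path / float(t[mask][-1] - t[mask][0])
    dia = float(pdist(theta).max()) if theta.shape[0] > 1 else 0.0
    return dia, speed


def extract_poco(rec: TaskRecording) -> dict:
    """Six posturography parameters: per-phase deflection range and sway speed
    plus the Romberg ratios (closed-phase / open-phase value)."""
    if rec.task != "POCO":
        raise ExtractionError(f"expected POCO recording, got {rec.task}")
    cue = rec.cue_times[0]
    pre = preprocess(rec.sequence)
    t = pre.timestamps
    rng_o, spd_o = _sway_phase(pre, float(t[0]), cue - POCO_PHASE_GUARD_S)
    rng_c, spd_c = _sway_phase(pre, cue + POCO_PHASE_GUARD_S, float(t[-1]))
    out = {
        "poco_deflection_range_open": rng_o,
        "poco_sway_speed_open": spd_o,
        "poco_deflection_range_closed": rng_c,
        "poco_sway_speed_closed": spd_c,
    }
    # denominators below numerical noise (deg / deg-per-s) count as zero
    eps = 1e-9
    out["poco_romberg_range"] = (rng_c / rng_o if rng_o > eps
                                 else _Missing("open-phase deflection range is 0"))
    out["poco_romberg_speed"] = (spd_c / spd_o if spd_o > eps
                                 else _Missing("open-phase sway speed is 0"))
    return out


# --------------------------------------------------------------------------
# Step detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StepEvents:
    """Per-side forward-extremum event times and the merged step train."""

    left_times: np.ndarray
    right_times: np.ndarray
    left_peaks: np.ndarray      # signal value at each left event
    right_peaks: np.ndarray

    def __post_init__(self):
        for times in (self.left_times, self.right_times):
            if np.any(np.diff(times) <= 0):
                raise ExtractionError("per-side event times not strictly increasing")

    @property
    def merged_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.left_times, self.right_times]))

    @property
    def intervals(self) -> np.ndarray:
        iv = np.diff(self.merged_times)
        if np.any(iv <= 0):
            raise ExtractionError("non-positive inter-step interval")
        return iv


def _side_signal(pre: SkeletonSequence, side: str, landmark_pair: str) -> np.ndarray:
    if landmark_pair == "ankles":
        # forward (walk-direction) displacement relative to the spine base;
        # walking toward the camera means forward = -Z
        rel = pre.landmark(f"{side}_ankle")[:, 2] - pre.landmark("spine_base")[:, 2]
        return -rel
    if landmark_pair == "knees":
        # AP-V displacement magnitude relative to the standing baseline
        knee = pre.landmark(f"{side}_knee")[:, [1, 2]]
        baseline = np.median(knee, axis=0)
        return np.linalg.norm(knee - baseline, axis=1)
    raise ValueError(f"landmark_pair must be 'ankles' or 'knees', got {landmark_pair!r}")


def _refine_peaks(t: np.ndarray, sig: np.ndarray,
                  idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-frame peak refinement by parabolic interpolation.

    Event times quantized to the 30 Hz grid would leak ~3% spurious interval
    variability; fitting a parabola through each peak and its neighbours
    recovers the continuous-time extremum and its value.
    """
    times = t[idx].astype(float)
    values = sig[idx].astype(float)
    for k, i in enumerate(idx):
        if 0 < i < sig.size - 1:
            y0, y1, y2 = sig[i - 1], sig[i], sig[i + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:                          # proper local maximum
                offset = 0.5 * (y0 - y2) / denom
                dt = t[i + 1] - t[i]
                times[k] = t[i] + offset * dt
                values[k] = y1 - 0.25 * (y0 - y2) * offset
    return times, values


def detect_steps(pre: SkeletonSequence, landmark_pair: str = "ankles") -> StepEvents:
    """Per-side step events at local maxima of the forward excursion signal.

    Peaks need a prominence of :data:`STEP_PROMINENCE_FRACTION` times the
    signal SD (scale-free) and a per-side gap of :data:`STEP_MIN_GAP_S`; the
    merged event train must alternate sides.
    """
    t = pre.timestamps
    fs = 1.0 / pre.mean_dt
    sides = {}
    for side in ("left", "right"):
        sig = _side_signal(pre, side, landmark_pair)
        prominence = STEP_PROMINENCE_FRACTION * float(np.std(sig))
        if prominence <= 0:
            sides[side] = (np.array([]), np.array([]))
            continue
        idx, _ = find_peaks(sig, prominence=prominence,
                            distance=max(int(round(STEP_MIN_GAP_S * fs)), 1))
        sides[side] = _refine_peaks(t, sig, idx)
    n_total = sides["left"][0].size + sides["right"][0].size
    if n_total < 4:
        raise ExtractionError(f"too few steps ({n_total} events, need >= 4)")
    labels = np.concatenate([np.zeros(sides["left"][0].size),
                             np.ones(sides["right"][0].size)])
    order = np.argsort(np.concatenate([sides["left"][0], sides["right"][0]]))
    seq = labels[order]
    if np.any(seq[1:] == seq[:-1]):
        raise ExtractionError("step events do not alternate sides")
    return StepEvents(left_times=sides["left"][0], right_times=sides["right"][0],
                      left_peaks=sides["left"][1], right_peaks=sides["right"][1])


# --------------------------------------------------------------------------
# Walks
# --------------------------------------------------------------------------

def _progression_speed(pre: SkeletonSequence) -> float:
    """Least-squares slope of the spine-base advance over the central portion
    of the walk (excluding :data:`SPEED_FIT_MARGIN_M` after start and before
    stop)."""
    t = pre.timestamps
    advance = pre.landmark("spine_base")[0, 2] - pre.landmark("spine_base")[:, 2]
    total = float(advance[-1])
    if total < 2.0 * SPEED_FIT_MARGIN_M + 0.2:
        raise ExtractionError(
            f"walk covers only {total:.2f} m; cannot fit central portion")
    mask = (advance >= SPEED_FIT_MARGIN_M) & (advance <= total - SPEED_FIT_MARGIN_M)
    if mask.sum() < 5:
        raise ExtractionError("too few frames in the central walk portion")
    slope = np.polyfit(t[mask], advance[mask], 1)[0]
    if slope <= 0:
        raise ExtractionError("no forward progression")
    return float(slope)


def _require_recordings(recs: Sequence[TaskRecording], task: str, n: int = 3):
    recs = list(recs)
    if len(recs) != n:
        raise ExtractionError(f"{task} requires {n} recordings, got {len(recs)}")
    for r in recs:
        if r.task != task:
            raise ExtractionError(f"expected {task} recording, got {r.task}")
    return recs


def extract_scsw(recs: Sequence[TaskRecording]) -> dict:
    """Comfortable-speed walk: gait speed (m/s), step length (cm) and cadence
    (steps/min), averaged over the three recordings."""
    recs = _require_recordings(recs, "SCSW")
    speeds, lengths, cadences = [], [], []
    for rec in recs:
        pre = preprocess(rec.sequence)
        speeds.append(_progression_speed(pre))
        steps = detect_steps(pre, "ankles")
        cadences.append(60.0 / float(np.mean(steps.intervals)))
        t = pre.timestamps
        left_z = pre.landmark("left_ankle")[:, 2]
        right_z = pre.landmark("right_ankle")[:, 2]
        idx = np.searchsorted(t, steps.merged_times)
        idx = np.clip(idx, 0, t.size - 1)
        lengths.append(float(np.mean(np.abs(left_z[idx] - right_z[idx]))) * 100.0)
    return {
        "scsw_gait_speed": float(np.mean(speeds)),
        "scsw_step_length": float(np.mean(lengths)),
        "scsw_cadence": float(np.mean(cadences)),
    }


def extract_smsw(recs: Sequence[TaskRecording]) -> dict:
    """Maximum-speed walk: gait speed (m/s) averaged over three recordings."""
    recs = _require_recordings(recs, "SMSW")
    speeds = [_progression_speed(preprocess(r.sequence)) for r in recs]
    return {"smsw_gait_speed": float(np.mean(speeds))}


def extract_slw(recs: Sequence[TaskRecording]) -> dict:
    """Line walk: progression speed, SD of the ML trunk inclination (deg) and
    pooled SD of the arm elevation angles (deg), averaged over recordings."""
    recs = _require_recordings(recs, "SLW")
    speeds, trunk_sds, arm_sds = [], [], []
    for rec in recs:
        pre = preprocess(rec.sequence)
        speeds.append(_progression_speed(pre))
        trunk = pre.landmark("spine_shoulder") - pre.landmark("spine_base")
        ml_angle = np.rad2deg(np.arctan2(trunk[:, 0], trunk[:, 1]))
        trunk_sds.append(float(np.std(ml_angle, ddof=1)))
        variances = []
        for side in ("left", "right"):
            arm = pre.landmark(f"{side}_wrist") - pre.landmark(f"{side}_shoulder")
            elev = np.rad2deg(np.arctan2(arm[:, 1], np.hypot(arm[:, 0], arm[:, 2])))
            variances.append(float(np.var(elev, ddof=1)))
        arm_sds.append(float(np.sqrt(np.mean(variances))))
    return {
        "slw_progression_speed": float(np.mean(speeds)),
        "slw_trunk_sway_variability": float(np.mean(trunk_sds)),
        "slw_arm_movement_variability": float(np.mean(arm_sds)),
    }


# --------------------------------------------------------------------------
# SAS — sit-stand transitions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionWindow:
    """One sit-stand transition delimited by the 5%/95% height crossings."""

    start: float
    end: float
    direction: str              # "stand_up" | "sit_down"

    def __post_init__(self):
        if self.end <= self.start:
            raise ExtractionError("transition window end must be after start")
        if self.direction not in ("stand_up", "sit_down"):
            raise ExtractionError(f"unknown direction {self.direction!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float,
                   start: float, rising: bool) -> float:
    """First time after ``start`` at which y crosses ``level`` in the stated
    direction, linearly interpolated between frames."""
    valid = t >= start
    yv, tv = y[valid], t[valid]
    if rising:
        hit = (yv[:-1] < level) & (yv[1:] >= level)
    else:
        hit = (yv[:-1] > level) & (yv[1:] <= level)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        raise ExtractionError("no transition detected (threshold never crossed)")
    i = idx[0]
    frac = (level - yv[i]) / (yv[i + 1] - yv[i])
    return float(tv[i] + frac * (tv[i + 1] - tv[i]))


def detect_transitions(rec: TaskRecording) -> tuple[TransitionWindow, TransitionWindow]:
    """Detect the stand-up and sit-down windows of a SAS recording.

    Seated and standing spine-base heights are medians over the pre-cue span
    and the second half of the inter-cue span (quiet standing); each window
    runs between the times at which the height crosses 5% and 95% of the
    seated-to-standing difference, searched after the corresponding cue.
    """
    if rec.task != "SAS":
        raise ExtractionError(f"expected SAS recording, got {rec.task}")
    cue1, cue2 = rec.cue_times
    pre = preprocess(rec.sequence)
    t = pre.timestamps
    y = pre.landmark("spine_base")[:, 1]
    seated = float(np.median(y[t <= cue1]))
    standing_span = (t >= cue1 + 0.5 * (cue2 - cue1)) & (t <= cue2)
    if standing_span.sum() < 3:
        raise ExtractionError("no quiet standing span between the cues")
    standing = float(np.median(y[standing_span]))
    delta = standing - seated
    if delta < MIN_TRANSITION_HEIGHT_M:
        raise ExtractionError(
            f"no transition detected (height change {delta * 100:.1f} cm < "
            f"{MIN_TRANSITION_HEIGHT_M * 100:.0f} cm)")
    lo, hi = TRANSITION_THRESHOLDS
    level_lo, level_hi = seated + lo * delta, seated + hi * delta
    up = TransitionWindow(
        start=_crossing_time(t, y, level_lo, cue1, rising=True),
        end=_crossing_time(t, y, level_hi, cue1, rising=True),
        direction="stand_up")
    down = TransitionWindow(
        start=_crossing_time(t, y, level_hi, cue2, rising=False),
        end=_crossing_time(t, y, level_lo, cue2, rising=False),
        direction="sit_down")
    return up, down


def _window_ranges(pre: SkeletonSequence, win: TransitionWindow) -> tuple[float, float]:
    """(trunk AP range, hand AP range) in cm within one transition window."""
    t = pre.timestamps
    mask = (t >= win.start) & (t <= win.end)
    if mask.sum() < 2:
        raise ExtractionError("transition window contains fewer than 2 frames")
    trunk = (pre.landmark("spine_shoulder")[:, 2] - pre.landmark("spine_base")[:, 2])[mask]
    trunk_range = float(np.ptp(trunk)) * 100.0
    hand_range = max(
        float(np.ptp(pre.landmark("left_hand")[mask, 2])),
        float(np.ptp(pre.landmark("right_hand")[mask, 2])),
    ) * 100.0
    return trunk_range, hand_range


def extract_sas(recs: Sequence[TaskRecording]) -> dict:
    """Six sit-stand parameters: per-direction transition time (s), trunk AP
    deflection (cm) and the larger hand's AP range (cm), averaged over the
    three recordings."""
    recs = _require_recordings(recs, "SAS")
    acc = {k: [] for k in TASK_PARAMETERS["SAS"]}
    for rec in recs:
        pre = preprocess(rec.sequence)
        up, down = detect_transitions(rec)
        trunk_up, hand_up = _window_ranges(pre, up)
        trunk_down, hand_down = _window_ranges(pre, down)
        acc["sas_stand_up_time"].append(up.duration)
        acc["sas_stand_up_trunk_deflection"].append(trunk_up)
        acc["sas_stand_up_hand_deflection"].append(hand_up)
        acc["sas_sitting_down_time"].append(down.duration)
        acc["sas_sitting_down_trunk_deflection"].append(trunk_down)
        acc["sas_sitting_down_hand_deflection"].append(hand_down)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# --------------------------------------------------------------------------
# SIP — stepping in place
# --------------------------------------------------------------------------

def amplitude_asymmetry(amp_left: float, amp_right: float) -> float:
    """|A_L - A_R| / max(A_L, A_R) * 100 (percent)."""
    top = max(amp_left, amp_right)
    if top <= 0:
        raise ExtractionError("zero knee amplitude on both sides")
    return abs(amp_left - amp_right) / top * 100.0


def arrhythmicity(intervals: np.ndarray) -> float:
    """100 x coefficient of variation of the merged inter-step intervals."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise ExtractionError("need at least 2 inter-step intervals")
    return 100.0 * float(np.std(intervals, ddof=1) / np.mean(intervals))


def extract_sip(rec: TaskRecording) -> dict:
    """Stepping in place: cadence, mean knee displacement amplitude (cm),
    amplitude asymmetry (%) and arrhythmicity (%) from the knee AP-V
    excursion peaks."""
    if rec.task != "SIP":
        raise ExtractionError(f"expected SIP recording, got {rec.task}")
    pre = preprocess(rec.sequence)
    steps = detect_steps(pre, "knees")
    if steps.left_times.size < 2 or steps.right_times.size < 2:
        raise ExtractionError("too few steps on one side")
    amp_left = float(np.mean(steps.left_peaks)) * 100.0
    amp_right = float(np.mean(steps.right_peaks)) * 100.0
    iv = steps.intervals
    return {
        "sip_cadence": 60.0 / float(np.mean(iv)),
        "sip_knee_amplitude": (amp_left + amp_right) / 2.0,
        "sip_amplitude_asymmetry": amplitude_asymmetry(amp_left, amp_right),
        "sip_arrhythmicity": arrhythmicity(iv),
    }


# --------------------------------------------------------------------------
# Full task set
# --------------------------------------------------------------------------

_EXPECTED_COUNTS = {"POCO": 1, "SCSW": 3, "SMSW": 3, "SLW": 3, "SAS": 3, "SIP": 1}


def extract_all(recordings: Iterable[TaskRecording]) -> ParameterVector:
    """Extract the full 23-parameter vector from one subject's recordings.

    A missing task, a wrong recording count or a per-task extraction failure
    flags that task's parameters with the reason instead of aborting.
    """
    by_task: dict[str, list[TaskRecording]] = {}
    for rec in recordings:
        by_task.setdefault(rec.task, []).append(rec)
    for task, recs in by_task.items():
        recs.sort(key=lambda r: r.repetition)

    pv = ParameterVector()
    extractors = {
        "POCO": lambda recs: extract_poco(recs[0]),
        "SCSW": extract_scsw,
        "SMSW": extract_smsw,
        "SLW": extract_slw,
        "SAS": extract_sas,
        "SIP": lambda recs: extract_sip(recs[0]),
    }
    for task, expected_n in _EXPECTED_COUNTS.items():
        names = TASK_PARAMETERS[task]
        recs = by_task.get(task, [])
        if len(recs) != expected_n:
            reason = (f"{task} recording missing" if not recs else
                      f"{task}: expected {expected_n} recordings, got {len(recs)}")
            for name in names:
                pv.flag_missing(name, reason)
            continue
        try:
            values = extractors[task](recs)
        except ExtractionError as exc:
            for name in names:
                pv.flag_missing(name, f"{task}: {exc}")
            continue
        for name in names:
            v = values[name]
            if isinstance(v, _Missing):
                pv.flag_missing(name, v.reason)
            else:
                pv.set(name, v)
    return pv
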