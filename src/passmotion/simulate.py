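"""Synthetic skeleton recordings and synthetic cohorts with known ground truth.

The original study deposited no raw recordings, so this module is the stand-in
for its data: it generates (a) kinematically explicit skeleton time series for
the six PASS-MS tasks at Kinect-V2-like sampling, built so that every derived
parameter has a closed-form or directly stated ground-truth value, and (b)
parameter-level cohorts whose per-parameter distributions are calibrated to
the published group means and SDs.

The generators are deliberately minimal kinematic models, not biomechanics:
a rigid standing pose is animated with the specific signal each extractor
measures (circular sway of the pelvis, steady-state gait with sinusoidal
ankle excursions, smooth sit-stand height profiles with anterior-posterior
trunk/hand excursion bumps, antiphase knee-lift bump trains).  Landmark
jitter is isotropic Gaussian, independent per frame, default SD 1 mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import published
from .skeleton import (
    LANDMARKS,
    LANDMARK_SET,
    PARAMETER_NAMES,
    SkeletonSequence,
    SubjectRecord,
    TaskRecording,
)

__all__ = [
    "FS",
    "WALK_DISTANCE",
    "SwayParams",
    "WalkParams",
    "SasParams",
    "SipParams",
    "GroundTruthParameters",
    "CohortSpec",
    "TruncNormSpec",
    "standing_pose",
    "smoothstep",
    "smoothstep_window_fraction",
    "ground_truth_from_targets",
    "japanese_default_targets",
    "simulate_poco",
    "simulate_walk",
    "simulate_sas",
    "simulate_sip",
    "simulate_subject_recordings",
    "simulate_parameter_cohort",
    "cohort_spec_from_published",
]

#: Nominal sampling rate, Hz (Kinect V2 delivers ~30 Hz skeleton streams).
FS = 30.0

#: Usable walk path, meters (sensor range limits walks to about 4 m).
WALK_DISTANCE = 4.0

#: Subject start distance from the camera for walks, meters.
WALK_START_Z = 5.0

#: Subject distance for stationary tasks, meters.
STATION_Z = 2.5


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Standing pose
# --------------------------------------------------------------------------

# Vertical landmark levels as fractions of body height (classic anthropometric
# segment fractions, simplified); X half-widths likewise.
_POSE_Y = {
    "spine_base": 0.55, "spine_mid": 0.68, "spine_shoulder": 0.80,
    "neck": 0.84, "head": 0.93,
    "shoulder": 0.80, "elbow": 0.63, "wrist": 0.47, "hand": 0.42,
    "hand_tip": 0.38, "thumb": 0.42,
    "hip": 0.53, "knee": 0.28, "ankle": 0.05, "foot": 0.02,
}
_POSE_X = {
    "shoulder": 0.115, "elbow": 0.125, "wrist": 0.125, "hand": 0.125,
    "hand_tip": 0.125, "thumb": 0.105,
    "hip": 0.060, "knee": 0.070, "ankle": 0.070, "foot": 0.070,
}


def standing_pose(height_m: float = 1.67, z0: float = STATION_Z) -> np.ndarray:
    """(25, 3) upright pose facing the camera (toes toward -Z)."""
    pose = np.zeros((len(LANDMARKS), 3))
    for i, name in enumerate(LANDMARKS):
        part = name.split("_", 1)[1] if name.startswith(("left_", "right_")) else name
        sign = -1.0 if name.startswith("left_") else 1.0
        pose[i, 0] = sign * _POSE_X.get(part, 0.0) * height_m
        pose[i, 1] = _POSE_Y[part] * height_m
        pose[i, 2] = z0 - (0.07 * height_m if part == "foot" else 0.0)
    return pose


def _indices(names) -> np.ndarray:
    return np.array([LANDMARK_SET.index(n) for n in names])


_LEG_PARTS = ("knee", "ankle", "foot")
_LOWER = _indices([f"{s}_{p}" for s in ("left", "right") for p in _LEG_PARTS])
_UPPER = np.array([i for i in range(len(LANDMARKS)) if i not in set(_LOWER)])
_ARM_PARTS = ("elbow", "wrist", "hand", "hand_tip", "thumb")
_HANDS = _indices([f"{s}_{p}" for s in ("left", "right")
                   for p in ("wrist", "hand", "hand_tip", "thumb")])
_TRUNK_TOP = _indices(["spine_shoulder", "neck", "head",
                       "left_shoulder", "right_shoulder"])


# --------------------------------------------------------------------------
# Ground-truth parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SwayParams:
    """Circular postural sway: angular radius (deg) and revolution rate (Hz)."""
    radius_deg: float
    rate_hz: float

    def __post_init__(self):
        if self.radius_deg < 0:
            raise ValueError("sway radius must be >= 0")
        if self.rate_hz < 0:
            raise ValueError("sway rate must be >= 0")

    @property
    def mean_speed_deg_s(self) -> float:
        """Closed form: angular path length per second on a circle."""
        return 2.0 * np.pi * self.rate_hz * self.radius_deg

    @property
    def deflection_range_deg(self) -> float:
        """Closed form: diameter of the circular angular trajectory."""
        return 2.0 * self.radius_deg


@dataclass(frozen=True)
class WalkParams:
    """Steady-state gait: cadence (steps/min) and step length (m).

    Speed is derived, not stored: for a steady walk the identity
    ``speed = cadence * step_length / 60`` holds by construction.
    """
    cadence_spm: float
    step_length_m: float

    def __post_init__(self):
        if not (40.0 < self.cadence_spm < 200.0):
            raise ValueError(f"cadence {self.cadence_spm} outside (40, 200) steps/min")
        if self.step_length_m <= 0:
            raise ValueError("step length must be > 0")

    @property
    def speed_m_s(self) -> float:
        return self.cadence_spm * self.step_length_m / 60.0


@dataclass(frozen=True)
class SasParams:
    """Sit-stand transitions: profile durations (s) and AP excursions (m).

    ``*_duration_s`` is the full duration of the vertical height profile; the
    5%/95% detection rule recovers a fixed fraction of it (0.9 for a linear
    ramp, :func:`smoothstep_window_fraction` for the smoothstep profile).
    """
    stand_up_duration_s: float
    sit_down_duration_s: float
    trunk_up_m: float
    hand_up_m: float
    trunk_down_m: float
    hand_down_m: float
    profile: str = "smoothstep"

    def __post_init__(self):
        if self.stand_up_duration_s <= 0 or self.sit_down_duration_s <= 0:
            raise ValueError("transition durations must be > 0")
        for v in (self.trunk_up_m, self.hand_up_m, self.trunk_down_m, self.hand_down_m):
            if v < 0:
                raise ValueError("excursions must be >= 0")
        if self.profile not in ("smoothstep", "linear"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class SipParams:
    """Stepping in place: per-side knee displacement amplitudes (m), mean
    inter-step interval (s) and its coefficient of variation."""
    amplitude_left_m: float
    amplitude_right_m: float
    interval_mean_s: float
    interval_cv: float

    def __post_init__(self):
        if self.amplitude_left_m < 0 or self.amplitude_right_m < 0:
            raise ValueError("knee amplitudes must be >= 0")
        if self.interval_mean_s <= 0:
            raise ValueError("mean step interval must be > 0")
        if self.interval_cv < 0:
            raise ValueError("interval CV must be >= 0")


def smoothstep(u: np.ndarray) -> np.ndarray:
    """C1 monotone rise 3u^2 - 2u^3 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def smoothstep_window_fraction() -> float:
    """Fraction of the smoothstep profile duration between the 5% and 95%
    amplitude crossings (the quantity the transition detector measures)."""
    u1 = brentq(lambda u: smoothstep(np.array(u)) - 0.05, 0.0, 0.5)
    return 1.0 - 2.0 * u1


_PROFILE_FRACTION = {"linear": 0.9, "smoothstep": smoothstep_window_fraction()}


@dataclass(frozen=True)
class GroundTruthParameters:
    """Generating values for one subject's full task set."""

    poco_open: SwayParams
    poco_closed: SwayParams
    scsw: WalkParams
    smsw: WalkParams
    slw: WalkParams
    slw_trunk_lean_deg: float
    slw_arm_swing_deg: float
    sas: SasParams
    sip: SipParams
    noise_sd_m: float = 0.001
    height_m: float = 1.67

    def __post_init__(self):
        if self.noise_sd_m < 0:
            raise ValueError("noise SD must be >= 0")
        if self.slw_trunk_lean_deg < 0 or self.slw_arm_swing_deg < 0:
            raise ValueError("lean/arm amplitudes must be >= 0")

    def expected_parameters(self) -> dict[str, float]:
        """Parameter values an ideal extractor recovers from these settings."""
        k = _PROFILE_FRACTION[self.sas.profile]
        a_l, a_r = self.sip.amplitude_left_m, self.sip.amplitude_right_m
        a_max = max(a_l, a_r)
        open_, closed = self.poco_open, self.poco_closed
        out = {
            "poco_deflection_range_open": open_.deflection_range_deg,
            "poco_sway_speed_open": open_.mean_speed_deg_s,
            "poco_deflection_range_closed": closed.deflection_range_deg,
            "poco_sway_speed_closed": closed.mean_speed_deg_s,
            "scsw_gait_speed": self.scsw.speed_m_s,
            "scsw_step_length": self.scsw.step_length_m * 100.0,
            "scsw_cadence": self.scsw.cadence_spm,
            "smsw_gait_speed": self.smsw.speed_m_s,
            "slw_progression_speed": self.slw.speed_m_s,
            "slw_trunk_sway_variability": self.slw_trunk_lean_deg / np.sqrt(2.0),
            "slw_arm_movement_variability": self.slw_arm_swing_deg / np.sqrt(2.0),
            "sas_stand_up_time": k * self.sas.stand_up_duration_s,
            "sas_stand_up_trunk_deflection": self.sas.trunk_up_m * 100.0,
            "sas_stand_up_hand_deflection": self.sas.hand_up_m * 100.0,
            "sas_sitting_down_time": k * self.sas.sit_down_duration_s,
            "sas_sitting_down_trunk_deflection": self.sas.trunk_down_m * 100.0,
            "sas_sitting_down_hand_deflection": self.sas.hand_down_m * 100.0,
            "sip_cadence": 60.0 / self.sip.interval_mean_s,
            "sip_knee_amplitude": (a_l + a_r) / 2.0 * 100.0,
            "sip_amplitude_asymmetry":
                0.0 if a_max == 0 else abs(a_l - a_r) / a_max * 100.0,
            "sip_arrhythmicity": self.sip.interval_cv * 100.0,
        }
        out["poco_romberg_range"] = (
            closed.deflection_range_deg / open_.deflection_range_deg
            if open_.deflection_range_deg > 0 else np.nan)
        out["poco_romberg_speed"] = (
            closed.mean_speed_deg_s / open_.mean_speed_deg_s
            if open_.mean_speed_deg_s > 0 else np.nan)
        return out

    def perturbed(self, rng: np.random.Generator,
                  frac: float = 0.02) -> "GroundTruthParameters":
        """Repetition-level jitter: multiplicative noise on the magnitudes a
        subject varies between immediate repetitions."""
        if frac == 0:
            return self

        def m(lo=None, hi=None):
            v = 1.0 + frac * rng.standard_normal()
            return float(np.clip(v, 0.5, 1.5))

        scsw = WalkParams(np.clip(self.scsw.cadence_spm * m(), 45, 195),
                          self.scsw.step_length_m * m())
        smsw = WalkParams(np.clip(self.smsw.cadence_spm * m(), 45, 195),
                          self.smsw.step_length_m * m())
        slw = WalkParams(np.clip(self.slw.cadence_spm * m(), 45, 195),
                         self.slw.step_length_m * m())
        sas = replace(self.sas,
                      stand_up_duration_s=self.sas.stand_up_duration_s * m(),
                      sit_down_duration_s=self.sas.sit_down_duration_s * m(),
                      trunk_up_m=self.sas.trunk_up_m * m(),
                      hand_up_m=self.sas.hand_up_m * m(),
                      trunk_down_m=self.sas.trunk_down_m * m(),
                      hand_down_m=self.sas.hand_down_m * m())
        return replace(self, scsw=scsw, smsw=smsw, slw=slw, sas=sas,
                       slw_trunk_lean_deg=self.slw_trunk_lean_deg * m(),
                       slw_arm_swing_deg=self.slw_arm_swing_deg * m())


# --------------------------------------------------------------------------
# Calibration: parameter targets -> generating values
# --------------------------------------------------------------------------

def japanese_default_targets() -> dict[str, float]:
    """Published Japanese cohort means of the 23 parameters (reporting units)."""
    return {row.name: float(row.mean1) for row in published.PARAMETER_ROWS}


def ground_truth_from_targets(targets: Mapping[str, float],
                              height_m: float = 1.67,
                              noise_sd_m: float = 0.001,
                              profile: str = "smoothstep") -> GroundTruthParameters:
    """Invert the extractor definitions: choose generating values so that an
    ideal extraction recovers the given parameter targets.

    Targets are clipped to physically workable bounds (a cohort draw from the
    published normal marginals can stray into impossible values).  The walk
    tasks calibrate cadence and step length and let speed emerge; for the
    speed-only walks a fixed cadence is assumed and step length is derived.
    Romberg ratios are emergent (closed/open), never calibrated directly.
    """
    t = dict(targets)

    def clip(name, lo, hi, default):
        return float(np.clip(t.get(name, default), lo, hi))

    def sway(range_name, speed_name, d_range, d_speed):
        rng_deg = clip(range_name, 0.05, 10.0, d_range)
        spd = clip(speed_name, 0.01, 20.0, d_speed)
        radius = rng_deg / 2.0
        # physiological sway stays well below the 1 Hz sway-analysis band
        rate = min(spd / (2.0 * np.pi * radius), 0.8)
        return SwayParams(radius_deg=radius, rate_hz=rate)

    poco_open = sway("poco_deflection_range_open", "poco_sway_speed_open", 1.01, 0.22)
    poco_closed = sway("poco_deflection_range_closed", "poco_sway_speed_closed", 1.10, 0.31)

    scsw = WalkParams(
        cadence_spm=clip("scsw_cadence", 70.0, 180.0, 116.1),
        step_length_m=clip("scsw_step_length", 35.0, 100.0, 67.19) / 100.0,
    )

    v_max = clip("smsw_gait_speed", 0.7, 2.6, 1.79)
    step_max = v_max * 60.0 / 140.0
    if step_max > 1.0:
        smsw = WalkParams(cadence_spm=60.0 * v_max, step_length_m=1.0)
    else:
        smsw = WalkParams(cadence_spm=140.0, step_length_m=step_max)

    v_line = clip("slw_progression_speed", 0.08, 1.2, 0.37)
    slw = WalkParams(cadence_spm=90.0, step_length_m=v_line * 60.0 / 90.0)

    k = _PROFILE_FRACTION[profile]
    sas = SasParams(
        stand_up_duration_s=clip("sas_stand_up_time", 0.6, 2.5, 1.34) / k,
        sit_down_duration_s=clip("sas_sitting_down_time", 0.6, 2.5, 1.36) / k,
        trunk_up_m=clip("sas_stand_up_trunk_deflection", 0.0, 40.0, 14.2) / 100.0,
        hand_up_m=clip("sas_stand_up_hand_deflection", 0.0, 40.0, 7.24) / 100.0,
        trunk_down_m=clip("sas_sitting_down_trunk_deflection", 0.0, 40.0, 11.8) / 100.0,
        hand_down_m=clip("sas_sitting_down_hand_deflection", 0.0, 40.0, 5.6) / 100.0,
        profile=profile,
    )

    cadence_sip = clip("sip_cadence", 60.0, 180.0, 108.8)
    amp_mean = clip("sip_knee_amplitude", 2.0, 50.0, 23.6) / 100.0
    asym = clip("sip_amplitude_asymmetry", 0.0, 60.0, 6.73) / 100.0
    amp_hi = 2.0 * amp_mean / (2.0 - asym)
    amp_lo = amp_hi * (1.0 - asym)
    sip = SipParams(
        amplitude_left_m=amp_hi, amplitude_right_m=amp_lo,
        interval_mean_s=60.0 / cadence_sip,
        interval_cv=clip("sip_arrhythmicity", 0.0, 40.0, 8.97) / 100.0,
    )

    return GroundTruthParameters(
        poco_open=poco_open, poco_closed=poco_closed,
        scsw=scsw, smsw=smsw, slw=slw,
        slw_trunk_lean_deg=clip("slw_trunk_sway_variability", 0.0, 6.0, 1.32) * np.sqrt(2.0),
        slw_arm_swing_deg=clip("slw_arm_movement_variability", 0.0, 10.0, 3.44) * np.sqrt(2.0),
        sas=sas, sip=sip, noise_sd_m=noise_sd_m, height_m=height_m,
    )


def default_ground_truth(noise_sd_m: float = 0.001) -> GroundTruthParameters:
    """Defaults calibrated to the published Japanese cohort means."""
    return ground_truth_from_targets(japanese_default_targets(),
                                     noise_sd_m=noise_sd_m)


# --------------------------------------------------------------------------
# Task simulators
# --------------------------------------------------------------------------

def _finish(task: str, repetition: int, cues, t: np.ndarray, pos: np.ndarray,
            noise_sd: float, rng: np.random.Generator) -> TaskRecording:
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
    return TaskRecording(task=task, repetition=repetition, cue_times=tuple(cues),
                         sequence=SkeletonSequence(t, pos))


def simulate_poco(gt: GroundTruthParameters,
                  duration_open: float = 20.0,
                  duration_closed: float = 20.0,
                  seed=0, repetition: int = 1) -> TaskRecording:
    """Quiet stance, eyes open then closed; one cue at the phase boundary.

    The pelvis (and everything above the knees) traces a circular angular path
    about the ankle midpoint: angular radius and revolution rate are set per
    phase, so mean angular sway speed is ``2*pi*rate*radius`` and the angular
    deflection range (trajectory diameter) is ``2*radius`` in closed form.
    Feet stay planted (closed-feet stance).
    """
    if duration_open <= 0 or duration_closed <= 0:
        raise ValueError("phase durations must be > 0")
    rng = _rng(seed)
    n = int(round((duration_open + duration_closed) * FS)) + 1
    t = np.arange(n) / FS
    pose = standing_pose(gt.height_m, STATION_Z)
    ankle_mid_y = pose[[LANDMARK_SET.index("left_ankle"),
                        LANDMARK_SET.index("right_ankle")], 1].mean()
    h = pose[LANDMARK_SET.index("spine_base"), 1] - ankle_mid_y

    open_mask = t < duration_open
    phi = np.empty(n)
    phi[open_mask] = 2.0 * np.pi * gt.poco_open.rate_hz * t[open_mask]
    phi_end = 2.0 * np.pi * gt.poco_open.rate_hz * duration_open
    phi[~open_mask] = phi_end + 2.0 * np.pi * gt.poco_closed.rate_hz * (
        t[~open_mask] - duration_open)
    radius = np.where(open_mask, gt.poco_open.radius_deg, gt.poco_closed.radius_deg)
    rho = h * np.tan(np.deg2rad(radius))

    pos = np.broadcast_to(pose, (n,) + pose.shape).copy()
    pos[:, _UPPER, 0] += (rho * np.cos(phi))[:, None]
    pos[:, _UPPER, 2] += (rho * np.sin(phi))[:, None]
    return _finish("POCO", repetition, (duration_open,), t, pos, gt.noise_sd_m, rng)


def simulate_walk(gt: GroundTruthParameters, task: str = "SCSW",
                  seed=0, repetition: int = 1) -> TaskRecording:
    """Steady-state walk toward the camera over the fixed 4 m path.

    The pelvis advances at the constant speed implied by cadence and step
    length; the ankles oscillate in the walk direction around the pelvis at
    half the cadence with amplitude ``step_length / 2``, in antiphase, so the
    leading-trailing ankle separation at a forward-extremum event equals the
    step length.  For the line walk ("SLW"), sinusoidal medio-lateral trunk
    lean and vertical arm-angle oscillation of the stated amplitudes are added
    (a sinusoid of amplitude ``a`` has standard deviation ``a / sqrt(2)``).
    """
    if task not in ("SCSW", "SMSW", "SLW"):
        raise ValueError(f"not a walk task: {task!r}")
    wp: WalkParams = getattr(gt, task.lower())
    rng = _rng(seed)
    v = wp.speed_m_s
    duration = WALK_DISTANCE / v
    n = int(round(duration * FS)) + 1
    t = np.arange(n) / FS
    pose = standing_pose(gt.height_m, WALK_START_Z)

    pos = np.broadcast_to(pose, (n,) + pose.shape).copy()
    dz = -v * t                                  # advance toward the camera
    pos[:, :, 2] += dz[:, None]

    f_stride = wp.cadence_spm / 120.0            # one stride = two steps
    amp = wp.step_length_m / 2.0
    swing = amp * np.cos(2.0 * np.pi * f_stride * t)
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        for part, gain in (("ankle", 1.0), ("foot", 1.0), ("knee", 0.5)):
            pos[:, LANDMARK_SET.index(f"{side}_{part}"), 2] += sgn * gain * swing

    if task == "SLW":
        base_i = LANDMARK_SET.index("spine_base")
        trunk_len = pose[LANDMARK_SET.index("spine_shoulder"), 1] - pose[base_i, 1]
        theta = np.deg2rad(gt.slw_trunk_lean_deg) * np.sin(2.0 * np.pi * f_stride * t)
        # tilt everything above the spine base in the ML plane about it
        lean_dx = trunk_len * np.sin(theta)
        lean_dy = trunk_len * (np.cos(theta) - 1.0)
        pos[:, _TRUNK_TOP, 0] += lean_dx[:, None]
        pos[:, _TRUNK_TOP, 1] += lean_dy[:, None]

        arm_len = 0.30 * gt.height_m
        theta0 = np.deg2rad(25.0)
        a_arm = np.deg2rad(gt.slw_arm_swing_deg)
        for side, phase in (("left", 0.0), ("right", np.pi)):
            th = theta0 + a_arm * np.sin(2.0 * np.pi * f_stride * t + phase)
            sh = pos[:, LANDMARK_SET.index(f"{side}_shoulder"), :]
            for part, ext in (("elbow", 0.5), ("wrist", 1.0), ("hand", 1.1),
                              ("hand_tip", 1.2), ("thumb", 1.05)):
                i = LANDMARK_SET.index(f"{side}_{part}")
                pos[:, i, 0] = sh[:, 0]
                pos[:, i, 1] = sh[:, 1] - ext * arm_len * np.cos(th)
                pos[:, i, 2] = sh[:, 2] - ext * arm_len * np.sin(th)

    return _finish(task, repetition, (), t, pos, gt.noise_sd_m, rng)


def simulate_sas(gt: GroundTruthParameters, seed=0,
                 repetition: int = 1) -> TaskRecording:
    """Stand up and sit down with two cues at the transition starts.

    The pelvis height follows seated level -> monotone rise (linear ramp or
    smoothstep, per ``gt.sas.profile``) -> standing level -> fall.  During
    each transition, the trunk (shoulder center relative to spine base) and
    both hands make anterior-posterior excursion bumps whose full range lies
    strictly inside the 5%/95% detection window, so the extracted deflections
    equal the generating amplitudes.
    """
    sas = gt.sas
    rng = _rng(seed)
    pre, hold, post = 3.0, 4.0, 2.0
    cue1 = pre
    cue2 = cue1 + sas.stand_up_duration_s + hold
    total = cue2 + sas.sit_down_duration_s + post
    n = int(round(total * FS)) + 1
    t = np.arange(n) / FS

    pose = standing_pose(gt.height_m, STATION_Z)
    standing_y = pose[LANDMARK_SET.index("spine_base"), 1]
    seated_y = 0.28 * gt.height_m
    delta = standing_y - seated_y

    prof = smoothstep if sas.profile == "smoothstep" else lambda u: np.clip(u, 0.0, 1.0)
    u_up = (t - cue1) / sas.stand_up_duration_s
    u_down = (t - cue2) / sas.sit_down_duration_s
    height = seated_y + delta * (prof(u_up) - prof(u_down))
    dy = height - standing_y                      # <= 0; 0 while standing

    pos = np.broadcast_to(pose, (n,) + pose.shape).copy()
    body = _indices(["spine_base", "spine_mid", "spine_shoulder", "neck", "head",
                     "left_hip", "right_hip",
                     "left_shoulder", "right_shoulder",
                     "left_elbow", "right_elbow"])
    pos[:, np.concatenate([body, _HANDS]), 1] += dy[:, None]

    def bump(u):
        inside = (u >= 0.2) & (u <= 0.8)
        b = np.zeros_like(u)
        b[inside] = np.sin(np.pi * (u[inside] - 0.2) / 0.6) ** 2
        return b

    trunk_ap = -(sas.trunk_up_m * bump(u_up) + sas.trunk_down_m * bump(u_down))
    hand_ap = -(sas.hand_up_m * bump(u_up) + sas.hand_down_m * bump(u_down))
    pos[:, _TRUNK_TOP, 2] += trunk_ap[:, None]
    pos[:, _HANDS, 2] += hand_ap[:, None]
    return _finish("SAS", repetition, (cue1, cue2), t, pos, gt.noise_sd_m, rng)


def simulate_sip(gt: GroundTruthParameters, duration: float = 40.0,
                 seed=0, repetition: int = 1) -> TaskRecording:
    """Stepping in place: antiphase knee-lift bumps in the AP-V plane.

    Step event times alternate sides; inter-step intervals are drawn from a
    normal with the stated mean and CV (seeded, floored at 0.3x the mean), so
    the extracted arrhythmicity is the sample CV of those intervals and the
    cadence is 60 / mean interval.  Each lift is a raised-sine bump whose peak
    displacement magnitude equals the per-side amplitude.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    sip = gt.sip
    rng = _rng(seed)
    n = int(round(duration * FS)) + 1
    t = np.arange(n) / FS

    events: list[tuple[float, int]] = []
    tc, side = 2.0, 0
    while tc < duration - 2.0:
        events.append((tc, side))
        step = rng.normal(sip.interval_mean_s, sip.interval_cv * sip.interval_mean_s)
        tc += max(step, 0.3 * sip.interval_mean_s)
        side = 1 - side

    pose = standing_pose(gt.height_m, STATION_Z)
    pos = np.broadcast_to(pose, (n,) + pose.shape).copy()
    width = 0.4 * sip.interval_mean_s
    elev = np.deg2rad(55.0)                       # knee lifts mostly upward
    direction = np.array([np.sin(elev), -np.cos(elev)])   # (V, AP) unit
    amps = (sip.amplitude_left_m, sip.amplitude_right_m)
    knees = (LANDMARK_SET.index("left_knee"), LANDMARK_SET.index("right_knee"))
    for te, s in events:
        mask = np.abs(t - te) <= width
        b = np.sin(np.pi * (t[mask] - te + width) / (2.0 * width)) ** 2
        pos[mask, knees[s], 1] += amps[s] * direction[0] * b
        pos[mask, knees[s], 2] += amps[s] * direction[1] * b
    return _finish("SIP", repetition, (), t, pos, gt.noise_sd_m, rng)


#: Simulation order of the 14 recordings per subject (task, repetition).
SUBJECT_RECORDING_PLAN: tuple[tuple[str, int], ...] = (
    (("POCO", 1),)
    + tuple(("SCSW", k) for k in (1, 2, 3))
    + tuple(("SMSW", k) for k in (1, 2, 3))
    + tuple(("SLW", k) for k in (1, 2, 3))
    + tuple(("SAS", k) for k in (1, 2, 3))
    + (("SIP", 1),)
)


def simulate_subject_recordings(gt: GroundTruthParameters, seed=0,
                                repetition_jitter: float = 0.0
                                ) -> list[TaskRecording]:
    """Full task set for one subject: three recordings each for SAS and the
    three walks (one measurement plus two immediate repetitions), one each
    for POCO and SIP — 14 recordings.

    The single seed is expanded into one child seed per (task, repetition)
    slot of :data:`SUBJECT_RECORDING_PLAN` via ``numpy.random.SeedSequence``,
    so streams are independent and the whole set is reproducible.  With
    ``repetition_jitter`` > 0, the generating magnitudes are multiplicatively
    perturbed per repetition before simulation.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(SUBJECT_RECORDING_PLAN))
    recordings = []
    for (task, rep), child in zip(SUBJECT_RECORDING_PLAN, children):
        rng = np.random.default_rng(child)
        gt_rep = gt.perturbed(rng, repetition_jitter) if repetition_jitter > 0 else gt
        if task == "POCO":
            rec = simulate_poco(gt_rep, seed=rng, repetition=rep)
        elif task == "SAS":
            rec = simulate_sas(gt_rep, seed=rng, repetition=rep)
        elif task == "SIP":
            rec = simulate_sip(gt_rep, seed=rng, repetition=rep)
        else:
            rec = simulate_walk(gt_rep, task=task, seed=rng, repetition=rep)
        recordings.append(rec)
    return recordings


# --------------------------------------------------------------------------
# Parameter-level cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormSpec:
    """Truncated normal: mean/SD with hard bounds (published range)."""
    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("SD must be >= 0")
        if not (self.lower < self.upper):
            raise ValueError("infeasible truncation bounds")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                             size=n, random_state=rng)


#: Default standardized height coefficients for stature-linked parameters.
#: Step length scales with leg length; both walk speeds inherit part of that.
DEFAULT_HEIGHT_BETA = {
    "scsw_step_length": 0.5,
    "scsw_gait_speed": 0.4,
    "smsw_gait_speed": 0.4,
}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of one cohort.

    ``parameters`` maps each of the 23 parameter names to (mean, SD) in
    reporting units; ``height_beta`` gives standardized linear height
    coefficients for stature-linked parameters.  Generation preserves the
    marginal mean/SD of every parameter regardless of ``height_beta``.
    """
    name: str
    n: int
    n_female: int
    age: TruncNormSpec
    height_cm: TruncNormSpec
    weight_kg: TruncNormSpec
    parameters: Mapping[str, tuple[float, float]]
    height_beta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if not (0 <= self.n_female <= self.n):
            raise ValueError("n_female outside [0, n]")
        for name, (mean, sd) in self.parameters.items():
            if sd < 0:
                raise ValueError(f"{name}: SD must be >= 0")
        for name, b in self.height_beta.items():
            if abs(b) > 1:
                raise ValueError(f"{name}: |height beta| must be <= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        def tn(key):
            v = d[key]
            return TruncNormSpec(v["mean"], v["sd"], v["lower"], v["upper"])
        return cls(
            name=d["name"], n=int(d["n"]), n_female=int(d["n_female"]),
            age=tn("age"), height_cm=tn("height_cm"), weight_kg=tn("weight_kg"),
            parameters={k: (float(m), float(s))
                        for k, (m, s) in d["parameters"].items()},
            height_beta=dict(d.get("height_beta", {})),
        )


def cohort_spec_from_published(label: str, n: int | None = None) -> CohortSpec:
    """Cohort spec calibrated to the published descriptives of one cohort."""
    if label not in published.COHORT_LABELS:
        raise ValueError(f"unknown cohort {label!r}")
    col = 0 if label == "Japanese" else 1
    chars = {row.name: row for row in published.CHARACTERISTIC_ROWS}

    def tn(name):
        row = chars[name]
        mean, sd = (float(row.mean1), float(row.sd1)) if col == 0 \
            else (float(row.mean2), float(row.sd2))
        lo, hi = published.STATURE_RANGES[(name, label)]
        return TruncNormSpec(mean, sd, lo, hi)

    params = {}
    for row in published.PARAMETER_ROWS:
        mean, sd = (float(row.mean1), float(row.sd1)) if col == 0 \
            else (float(row.mean2), float(row.sd2))
        params[row.name] = (mean, sd)
    n_total = n if n is not None else published.N_PER_COHORT
    n_female = published.SEX_COUNTS[0][col]
    if n is not None:
        n_female = int(round(n * published.SEX_COUNTS[0][col] / published.N_PER_COHORT))
    return CohortSpec(
        name=label, n=n_total, n_female=n_female,
        age=tn("age_years"), height_cm=tn("height_cm"), weight_kg=tn("weight_kg"),
        parameters=params, height_beta=dict(DEFAULT_HEIGHT_BETA),
    )


def simulate_parameter_cohort(spec: CohortSpec, seed=0):
    """Draw subjects and a 23-column parameter table for one cohort.

    Stature comes from truncated normals at the spec's moments; parameters
    come from normals at the spec's means/SDs.  A parameter with a height
    coefficient ``b`` is generated as
    ``mean + sd * (b * z_height + sqrt(1 - b^2) * eps)``, which preserves the
    marginal mean and SD exactly in distribution.  Parameter values are *not*
    truncated: the table emulates the published moments, not the physical
    support (see the methods note).

    Returns
    -------
    (subjects, table) : list of :class:`SubjectRecord`, pandas.DataFrame
        ``table`` is indexed by subject id with the 23 parameter columns.
    """
    import pandas as pd

    rng = _rng(seed)
    heights = spec.height_cm.sample(spec.n, rng)
    weights = spec.weight_kg.sample(spec.n, rng)
    ages = spec.age.sample(spec.n, rng)
    sexes = ["F"] * spec.n_female + ["M"] * (spec.n - spec.n_female)
    prefix = spec.name.lower().replace(" ", "_")
    subjects = [
        SubjectRecord(subject_id=f"{prefix}_{i + 1:03d}", cohort=spec.name,
                      sex=sexes[i], age=float(ages[i]),
                      height_cm=float(heights[i]), weight_kg=float(weights[i]))
        for i in range(spec.n)
    ]

    # standardize by the truncated-normal moments so the height link carries
    # exactly the stated standardized coefficient and the parameter marginals
    # keep their stated mean/SD
    if spec.height_cm.sd > 0:
        hs = spec.height_cm
        a = (hs.lower - hs.mean) / hs.sd
        b_ = (hs.upper - hs.mean) / hs.sd
        m_t, v_t = truncnorm.stats(a, b_, loc=hs.mean, scale=hs.sd, moments="mv")
        z_h = (heights - float(m_t)) / float(np.sqrt(v_t))
    else:
        z_h = np.zeros(spec.n)
    data = {}
    for name in PARAMETER_NAMES:
        if name not in spec.parameters:
            raise ValueError(f"cohort spec {spec.name!r} missing parameter {name!r}")
        mean, sd = spec.parameters[name]
        b = float(spec.height_beta.get(name, 0.0))
        eps = rng.standard_normal(spec.n)
        data[name] = mean + sd * (b * z_h + np.sqrt(1.0 - b * b) * eps)
    table = pd.DataFrame(data, index=[s.subject_id for s in subjects])
    table.index.name = "subject_id"
    return subjects, table
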