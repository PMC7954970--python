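"""Published reference statistics of the original Japanese/German cohort study.

The study that this package reimplements compared 25 healthy Japanese and 25
matched German adults on the six PASS-MS motor tasks and published, per
parameter and cohort, the mean, SD, coefficient of variation, the two-sided
*t*-test p-value, and Cohen's d (German minus Japanese, pooled SD).  Raw data
were not deposited, so these printed summary cells are the only quantitative
anchor available:

* they are the calibration targets of the synthetic cohort generator, and
* the effect-size/CV verifier recomputes every derivable quantity from them.

Values are stored as the exact printed strings so that the number of printed
decimals — and hence the half-ULP rounding uncertainty of each cell — is
preserved.  All printed cells are N = 25 per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "N_PER_COHORT",
    "COHORT_LABELS",
    "SEX_COUNTS",
    "CHARACTERISTIC_ROWS",
    "PARAMETER_ROWS",
    "STATURE_RANGES",
    "PublishedRow",
    "half_ulp",
]

N_PER_COHORT = 25
COHORT_LABELS = ("Japanese", "German")

#: 2x2 sex contingency counts (rows F/M, columns Japanese/German) and the
#: published chi-square p-value.
SEX_COUNTS = ((11, 12), (14, 13))
SEX_CHI2_P = 0.776


def half_ulp(printed: str) -> float:
    """Half of the last printed decimal place of a number string."""
    s = printed.lstrip("+-")
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 0.5 * 10.0 ** (-decimals)


@dataclass(frozen=True)
class PublishedRow:
    """One published comparison row: group moments plus printed d (and CVs)."""

    name: str
    mean1: str          # Japanese mean
    sd1: str            # Japanese SD
    mean2: str          # German mean
    sd2: str            # German SD
    d: str              # printed Cohen's d, sign = German - Japanese
    p: str              # printed t-test p-value
    cv1: str | None = None
    cv2: str | None = None

    def floats(self) -> tuple[float, float, float, float]:
        return float(self.mean1), float(self.sd1), float(self.mean2), float(self.sd2)


#: Subject characteristics (age, stature) of the two cohorts.
CHARACTERISTIC_ROWS: tuple[PublishedRow, ...] = (
    PublishedRow("age_years", "30.3", "6.2", "31.5", "5.09", "0.211", ".458"),
    PublishedRow("height_cm", "166.8", "8.8", "173.6", "9.9", "0.729", ".013"),
    PublishedRow("weight_kg", "60.3", "9.4", "68.8", "9.5", "0.902", ".002"),
    PublishedRow("bmi", "21.6", "1.9", "22.8", "2.4", "0.562", ".053"),
)

#: Published ranges (min-max) used as truncation bounds for stature sampling,
#: keyed by (row name, cohort label).
STATURE_RANGES = {
    ("age_years", "Japanese"): (23.0, 35.0),
    ("age_years", "German"): (22.0, 39.0),
    ("height_cm", "Japanese"): (153.0, 185.0),
    ("height_cm", "German"): (156.0, 190.0),
    ("weight_kg", "Japanese"): (48.0, 90.0),
    ("weight_kg", "German"): (51.0, 88.0),
    ("bmi", "Japanese"): (18.9, 27.2),
    ("bmi", "German"): (18.9, 28.2),
}

#: The 23 spatiotemporal parameters, in report order (names match
#: :data:`passmotion.skeleton.PARAMETER_NAMES`).
PARAMETER_ROWS: tuple[PublishedRow, ...] = (
    PublishedRow("poco_deflection_range_open", "1.01", "0.55", "0.80", "0.41",
                 "-0.43", ".135", "0.54", "0.5"),
    PublishedRow("poco_sway_speed_open", "0.22", "0.08", "0.19", "0.05",
                 "-0.30", ".297", "0.39", "0.27"),
    PublishedRow("poco_deflection_range_closed", "1.10", "0.41", "1.03", "0.56",
                 "-0.15", ".609", "0.37", "0.53"),
    PublishedRow("poco_sway_speed_closed", "0.31", "0.09", "0.26", "0.10",
                 "-0.53", ".065", "0.29", "0.37"),
    PublishedRow("poco_romberg_range", "1.32", "0.65", "1.43", "0.74",
                 "0.16", ".563", "0.49", "0.51"),
    PublishedRow("poco_romberg_speed", "1.55", "0.48", "1.37", "0.46",
                 "-0.37", ".199", "0.31", "0.33"),
    PublishedRow("scsw_gait_speed", "1.16", "0.14", "1.16", "0.18",
                 "-0.03", ".923", "0.12", "0.16"),
    PublishedRow("scsw_step_length", "67.19", "7.86", "69.41", "8.06",
                 "0.28", ".327", "0.12", "0.12"),
    PublishedRow("scsw_cadence", "116.1", "7.3", "110.8", "10.7",
                 "-0.57", ".049", "0.06", "0.10"),
    PublishedRow("smsw_gait_speed", "1.79", "0.18", "1.73", "0.16",
                 "-0.38", ".185", "0.10", "0.09"),
    PublishedRow("slw_progression_speed", "0.37", "0.09", "0.34", "0.07",
                 "-0.40", ".164", "0.24", "0.19"),
    PublishedRow("slw_trunk_sway_variability", "1.32", "0.92", "1.94", "1.0",
                 "0.65", ".026", "0.70", "0.47"),
    PublishedRow("slw_arm_movement_variability", "3.44", "2.26", "5.64", "3.67",
                 "0.71", ".015", "0.66", "0.65"),
    PublishedRow("sas_stand_up_time", "1.34", "0.19", "1.50", "0.18",
                 "0.86", ".004", "0.14", "0.12"),
    PublishedRow("sas_stand_up_trunk_deflection", "14.2", "2.84", "14.7", "2.80",
                 "0.15", ".608", "0.20", "0.19"),
    PublishedRow("sas_stand_up_hand_deflection", "7.24", "3.0", "11.7", "4.3",
                 "1.19", ".000", "0.42", "0.37"),
    PublishedRow("sas_sitting_down_time", "1.36", "0.23", "1.61", "0.25",
                 "1.03", ".001", "0.16", "0.15"),
    PublishedRow("sas_sitting_down_trunk_deflection", "11.8", "2.58", "14.6", "2.98",
                 "1.01", ".001", "0.22", "0.20"),
    PublishedRow("sas_sitting_down_hand_deflection", "5.6", "2.43", "10.2", "2.88",
                 "1.72", ".000", "0.43", "0.28"),
    PublishedRow("sip_cadence", "108.8", "14.3", "104.3", "19.0",
                 "-0.27", ".351", "0.13", "0.18"),
    PublishedRow("sip_knee_amplitude", "23.6", "5.13", "19.8", "6.53",
                 "-0.65", ".025", "0.22", "0.33"),
    PublishedRow("sip_amplitude_asymmetry", "6.73", "5.77", "10.78", "9.72",
                 "0.51", ".079", "0.86", "0.90"),
    PublishedRow("sip_arrhythmicity", "8.97", "3.34", "8.58", "4.29",
                 "-0.10", ".719", "0.37", "0.50"),
)

#: CV cells that cannot be reproduced from their own printed mean/SD under any
#: rounding (source-internal inconsistency; see the methods note).
INCONSISTENT_CV_CELLS = (("slw_trunk_sway_variability", "German"),)
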