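"""Shared fixtures: deterministic ground-truth settings and tiny recordings."""

import dataclasses

import numpy as np
import pytest

from passmotion.simulate import (
    GroundTruthParameters,
    SwayParams,
    ground_truth_from_targets,
    japanese_default_targets,
)

#: Single a-priori seed for every stochastic check in the suite.
SEED = 1234


@pytest.fixture(scope="session")
def clean_gt() -> GroundTruthParameters:
    """Jitter-free generator calibrated to the published Japanese means."""
    return ground_truth_from_targets(japanese_default_targets(), noise_sd_m=0.0)


@pytest.fixture(scope="session")
def circle_gt(clean_gt) -> GroundTruthParameters:
    """Jitter-free generator with identical circular sway in both stance
    phases (radius 0.5 deg, 0.25 Hz) for closed-form posturography checks."""
    sway = SwayParams(radius_deg=0.5, rate_hz=0.25)
    return dataclasses.replace(clean_gt, poco_open=sway, poco_closed=sway)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
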