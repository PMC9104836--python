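"""Shared fixtures: optical profiles and small simulated datasets."""

import numpy as np
import pytest

from fpmkit import OpticalConfig, make_pupil, simulate_dataset, synthetic_ground_truth
from fpmkit.experiments import DEFAULT_ABERRATION, FULL_PROFILE, REDUCED_PROFILE


@pytest.fixture(scope="session")
def full_config():
    """The full simulation platform: 15x15 LEDs, 128^2 -> 384^2."""
    return FULL_PROFILE


@pytest.fixture(scope="session")
def reduced_config():
    """Desk-scale sweep profile: 9x9 LEDs, 64^2 -> 192^2."""
    return REDUCED_PROFILE


@pytest.fixture(scope="session")
def tiny_config():
    """Small profile for fast solver-level unit tests: 7x7 LEDs, 32^2 -> 96^2."""
    return OpticalConfig(
        led_rows=7, led_cols=7, led_pitch_mm=4.0, lr_side=32, hr_side=96
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_config):
    return synthetic_ground_truth(tiny_config.hr_side, seed=5)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tiny_truth):
    """Noiseless stack from an aberrated pupil on the tiny profile."""
    pupil = make_pupil(tiny_config, DEFAULT_ABERRATION)
    ms = simulate_dataset(tiny_config, tiny_truth, pupil, seed=5)
    return ms, tiny_truth, pupil


@pytest.fixture(scope="session")
def tiny_ideal_dataset(tiny_config, tiny_truth):
    """Noiseless stack from the ideal (aberration-free) pupil."""
    pupil = make_pupil(tiny_config)
    ms = simulate_dataset(tiny_config, tiny_truth, pupil, seed=5)
    return ms, tiny_truth, pupil


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
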