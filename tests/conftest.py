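import dataclasses

import numpy as np
import pytest

from precistep.protocol import (
    ProtocolParams,
    generate_perturbed_block,
    generate_unperturbed_block,
)
from precistep.synthetic import SubjectParams, simulate_trial


@pytest.fixture(scope="session")
def params():
    return ProtocolParams(preferred_step_length=0.5)


@pytest.fixture(scope="session")
def clean_subject():
    """Subject with realistic landing variability but no sensor noise."""
    return SubjectParams(
        subject_id="S001",
        age=14.0,
        sex="F",
        step_length=0.5,
        error_bias=0.01,
        sigma=0.05,
        marker_noise_sd=0.0,
        cop_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noisy_subject(clean_subject):
    return dataclasses.replace(
        clean_subject, marker_noise_sd=0.001, cop_noise_sd=0.002
    )


@pytest.fixture(scope="session")
def unperturbed_block(params):
    return generate_unperturbed_block(params)


@pytest.fixture(scope="session")
def perturbed_block(params):
    return generate_perturbed_block(params, rng=42)


@pytest.fixture(scope="session")
def clean_trial(clean_subject, unperturbed_block, params):
    """Noise-free 59-target unperturbed trial."""
    return simulate_trial(clean_subject, unperturbed_block, params, seed=5)


@pytest.fixture(scope="session")
def clean_perturbed_trial(clean_subject, perturbed_block, params):
    """Noise-free 248-target perturbed trial."""
    return simulate_trial(clean_subject, perturbed_block, params, seed=8)


@pytest.fixture(scope="session")
def noisy_trial(noisy_subject, unperturbed_block, params):
    return simulate_trial(noisy_subject, unperturbed_block, params, seed=5)


def all_event_times(d):
    return np.sort(np.concatenate([d["left"], d["right"]]))


def nearest_deviations(detected, truth):
    """Per detected event, distance to the nearest true event (seconds)."""
    return np.array([np.min(np.abs(truth - t)) for t in detected])
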