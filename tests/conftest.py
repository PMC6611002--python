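"""Shared fixtures.

The run/pirouette cohort pipeline is expensive (tens of seconds), so the
fixture is session-scoped and shared between the end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import steftr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def runpir_trajset():
    """The documented run/pirouette cohort: 50 animals x 600 frames, seed 1."""
    return steftr.simulate_state_switching(steftr.run_pirouette_spec(n_animals=50, n_frames=600, seed=1))


@pytest.fixture(scope="session")
def runpir_annotation(runpir_trajset):
    return steftr.estimate_states(runpir_trajset, steftr.EstimateConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 8-animal cohort for cheap end-to-end checks."""
    return steftr.simulate_state_switching(steftr.run_pirouette_spec(n_animals=8, n_frames=300, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
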