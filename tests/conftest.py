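"""Shared fixtures: small simulated recordings reused across test modules.

Session scope keeps the suite fast — the simulations are deterministic
(fixed seeds), so sharing them never couples tests.
"""

import numpy as np
import pytest

from lfpevents.pipeline import process_recording
from lfpevents.synthetic import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def sim120():
    """Two-minute default-world recording, seed 3."""
    return simulate_recording(SimConfig(seed=3, duration_s=120.0))


@pytest.fixture(scope="session")
def processed120(sim120):
    return process_recording(sim120.recording, sim120.probe)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
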