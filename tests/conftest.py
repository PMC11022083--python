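"""Shared fixtures: hand-built and randomly generated valid recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from limbkin import (
    Block,
    Event,
    Recording,
    RecordingMeta,
)
from limbkin.synth import random_recording as make_recording  # noqa: F401

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_recording() -> Recording:
    """One block, one event, three samples, no optional fields."""
    event = Event(
        event_id=0,
        block_id=0,
        sample_ids=np.arange(3),
        t=np.array([0.0, 0.01, 0.02]),
        accel=np.array([[0.0, 0.0, 9.81], [0.1, -0.2, 9.7], [0.05, 0.0, 9.9]]),
    )
    meta = RecordingMeta(n_blocks=1, n_events=1)
    return Recording([Block(0, [event])], meta)


@pytest.fixture
def random_recording(rng) -> Recording:
    return make_recording(rng)
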