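"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

import whiskvr as w

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def short_session():
    """120 s rendered session with 4 neurons; used by kinematics/io tests."""
    cfg = w.SessionConfig(duration=120.0, seed=2)
    specs = w.make_population(4, seed=2)
    return w.simulate_session(cfg, specs, render=True)


@pytest.fixture(scope="session")
def medium_session():
    """600 s unrendered session with 24 neurons; used by alignment/stats tests."""
    cfg = w.SessionConfig(duration=600.0, seed=7)
    specs = w.make_population(24, seed=7)
    return w.simulate_session(cfg, specs, render=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
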