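"""Shared fixtures: analysis config and a few synthetic sessions reused
across test modules (session generation + preprocessing dominates test
runtime, so sessions are module-cached at the largest useful scope)."""

from __future__ import annotations

import numpy as np
import pytest

from chisync.config import AnalysisConfig
from chisync.pipeline import preprocess_session
from chisync.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def acfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def basic_session():
    """300 s two-channel session with jerks, initiations and micro events."""
    return generate_session(SynthConfig(seed=7, duration_s=300.0))


@pytest.fixture(scope="session")
def basic_processed(basic_session, acfg):
    return preprocess_session(basic_session, acfg)


@pytest.fixture(scope="session")
def cell_session():
    """Session with 10 imaged cells, high onset participation and
    asynchronous locomotion firing (the synchrony-dissociation regime)."""
    return generate_session(SynthConfig(
        seed=5, duration_s=300.0, n_cells=10,
        participation_prob_onset=0.9, participation_prob_rest=0.6,
        async_rate_locomotion=0.5,
        jerk_rate_per_min=2.0, initiation_rate_per_min=2.0))


@pytest.fixture(scope="session")
def cell_processed(cell_session, acfg):
    return preprocess_session(cell_session, acfg)


def rng_noise_trace(seed, n=6000, sd=0.05):
    """i.i.d. Gaussian ΔF/F noise trace at 100 Hz (helper for tests)."""
    from chisync.preprocessing import DffTrace

    x = np.random.default_rng(seed).normal(0.0, sd, n)
    return DffTrace(dff=x, baseline=np.ones(n), bin_s=0.01)
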