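"""Shared fixtures: seeded RNGs, small sweeps, and the hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evacdem.metrics import compute_metrics
from evacdem.simulator import SimConfig, sweep

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def study_config():
    """Shared study-scale configuration: 20 agents, defaults elsewhere."""
    return SimConfig(n_agents=20)


@pytest.fixture(scope="session")
def smice_sweep(study_config):
    """6 angles x 3 cases x 20 agents with angle-dependent speed dispersion."""
    return sweep(study_config, cases=3, mode="smice", seed=0)


@pytest.fixture(scope="session")
def uniform_sweep(study_config):
    """The same sweep with the across-angle-uniform speed dispersion."""
    return sweep(study_config, cases=3, mode="uniform", seed=0)


@pytest.fixture(scope="session")
def smice_metrics(smice_sweep):
    return compute_metrics(smice_sweep.tracks, smice_sweep.events, smice_sweep.trials)


@pytest.fixture(scope="session")
def uniform_metrics(uniform_sweep):
    return compute_metrics(
        uniform_sweep.tracks, uniform_sweep.events, uniform_sweep.trials
    )
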