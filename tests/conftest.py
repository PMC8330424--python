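"""Shared fixtures: short, fast study configurations derived from the defaults."""

import numpy as np
import pytest

from synapsim import (
    EngineConfig,
    PostSynParams,
    PreSynParams,
    RunConfig,
    ScenarioSpec,
    periodic_spike_train,
)


@pytest.fixture(scope="session")
def presyn():
    return PreSynParams()


@pytest.fixture(scope="session")
def postsyn():
    return PostSynParams()


@pytest.fixture(scope="session")
def short_config():
    """Canonical protocol shortened to 2 s for unit-level engine tests."""
    return RunConfig(engine=EngineConfig(horizon=2.0, delta=2e-4))


@pytest.fixture(scope="session")
def scenario_config():
    """Scenario-comparison protocol: 6 s, coarse step, canonical drive."""
    return RunConfig(engine=EngineConfig(horizon=6.0, delta=2e-4))


@pytest.fixture(scope="session")
def baseline_run(scenario_config):
    """Healthy discretized run of the scenario protocol (computed once)."""
    return scenario_config.run()


@pytest.fixture(scope="session")
def spikes_10hz():
    return periodic_spike_train(10.0, 2.0)
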