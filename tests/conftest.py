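from __future__ import annotations

import pytest

from smartquit import BehaviorParams, StudyConfig, default_bank, run_engine, simulate_cohort


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture(scope="session")
def cohort59(config):
    """One full-size simulated cohort (n=59, seed 1), shared across tests."""
    return simulate_cohort(BehaviorParams(seed=1), config)


@pytest.fixture(scope="session")
def cohort59_messages(cohort59, bank, config):
    return run_engine(cohort59.events, bank, config, cohort59.participants)
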