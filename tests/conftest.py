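"""Shared fixtures: small simulated cohorts and recordings."""

import numpy as np
import pytest

from calquench import io_cli, synthdata


@pytest.fixture(scope="session")
def small_spec() -> synthdata.CohortSpec:
    """A fast, small cohort: few animals, few neurons, default physiology."""
    return synthdata.sham_baseline_spec(
        n_animals_per_group=3, neurons_min=20, neurons_max=30
    )


@pytest.fixture(scope="session")
def sham_recording(small_spec):
    """One seeded sham-baseline recording with its ground truth."""
    return synthdata.simulate_recording(small_spec, "baseline", seed=1234, group="sham")


@pytest.fixture(scope="session")
def fast_config() -> io_cli.RunConfig:
    """Pipeline config with a reduced shuffle count for unit tests."""
    return io_cli.RunConfig(events={"n_shuffles": 200})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
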