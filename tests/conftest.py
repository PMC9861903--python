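"""Shared fixtures: a ground-truthed synthetic dataset and its validation.

The expensive end-to-end objects are session-scoped so the acceptance
tests and the module tests can share one computation.
"""

import numpy as np
import pytest

from junctionqc import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def dataset42(default_config):
    """The standard misjoin-injection experiment: 5 Mb, 2 chromosomes,
    40 contigs, 8 misjoins, 2 enzyme channels, default noise, seed 42."""
    return sd.simulate_dataset(default_config)


@pytest.fixture(scope="session")
def result42(dataset42):
    return pipeline.run_validation(dataset42)


@pytest.fixture(scope="session")
def score42(result42, dataset42):
    return pipeline.score_against_truth(result42, dataset42)


@pytest.fixture(scope="session")
def null_runs():
    """Twenty no-misjoin runs with default noise (the null experiment)."""
    runs = []
    for seed in range(1, 21):
        ds = sd.simulate_dataset(sd.SimulationConfig(seed=seed, misjoins=()))
        runs.append((ds, pipeline.run_validation(ds)))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
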