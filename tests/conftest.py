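import logging

import numpy as np
import pytest
from hypothesis import settings

from isospec import SimulationConfig, simulate_dataset, truth_frame

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# non-converged-feature warnings are expected on a few degenerate features
logging.getLogger("isospec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted scenario: 5 subtypes x 30 samples/split, ~2000 isoforms."""
    cfg = SimulationConfig(seed=7)
    x, samples, annotation, truth = simulate_dataset(cfg)
    return cfg, x, samples, annotation, truth


@pytest.fixture(scope="session")
def planted_truth_frame(planted_dataset):
    return truth_frame(planted_dataset[4])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
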