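import numpy as np
import pandas as pd
import pytest

from tatamisom import RunConfig, analyze, simulate_dataset


@pytest.fixture(scope="session")
def synthetic():
    """Default-scale synthetic study: counts, meta, secretome, truth."""
    return simulate_dataset(n_genes=2000, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def result(synthetic):
    """Full analysis of the default synthetic study (437-unit map)."""
    counts, meta, secretome, truth = synthetic
    return analyze(counts, meta, secretome, RunConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_meta():
    return pd.DataFrame(
        {
            "sample_id": ["c_r1", "c_r2", "d_r1", "d_r2"],
            "condition": ["control", "control", "D4", "D4"],
            "replicate": [1, 2, 1, 2],
        }
    )
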