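import numpy as np
import pandas as pd
import pytest

from methdyn import RunConfig, SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study reused by the integration tests."""
    params = SimulationParams(
        n_genes=800,
        n_cpgs=4000,
        n_dynamic_genes=20,
        n_cea_genes=30,
        n_mea_pairs=20,
        rng_seed=101,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(rng_seed=202, n_permutations=200)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_expr():
    return pd.DataFrame(
        [[0.0, 1.5], [3.0, 0.0]],
        index=["geneA", "geneB"],
        columns=["Day1", "Day2"],
    )
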