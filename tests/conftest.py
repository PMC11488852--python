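import numpy as np
import pandas as pd
import pytest

from protoy.de import filter_low_expression, normalize_vst
from protoy.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def two_block_dataset():
    """Counts with two planted 50-gene modules plus background, VST-normalized."""
    config = SimConfig(
        n_genes=300, n_samples=24, seed=1, module_spec=[(50, 0.8), (50, 0.8)]
    )
    counts, meta, truth = simulate_counts(config)
    expr = normalize_vst(filter_low_expression(counts))
    return counts, meta, truth, expr


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_corr(rng):
    """A valid correlation matrix from a random 10-gene expression fixture."""
    x = pd.DataFrame(
        rng.normal(size=(10, 15)),
        index=[f"g{i:02d}" for i in range(10)],
        columns=[f"s{i}" for i in range(15)],
    )
    from protoy.network import correlation_matrix

    return correlation_matrix(x)
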