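import warnings

import numpy as np
import pandas as pd
import pytest

from cernet import synthetic

# scanpy emits benign FutureWarnings from its own deps; keep test output clean
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def bulk_default():
    """One bulk dataset at generator defaults (8 cases vs 6 controls)."""
    return synthetic.generate_bulk_circrna(synthetic.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def sc_default():
    """One single-cell dataset at generator defaults (500 cells, 4 types)."""
    return synthetic.generate_scrna(synthetic.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def pools_default():
    """Sequence pools realising five planted sponge triplets."""
    return synthetic.generate_sequences(synthetic.GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_matrix(rng):
    """20 features x 12 samples of pure noise, log2-like scale."""
    x = rng.normal(8.0, 1.0, size=(20, 12))
    return pd.DataFrame(
        x,
        index=[f"f{i:02d}" for i in range(20)],
        columns=[f"s{j}" for j in range(12)],
    )
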