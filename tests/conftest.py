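import numpy as np
import pytest

from qsarcov import TableSimConfig, simulate_model_table


@pytest.fixture(scope="session")
def default_table():
    """One benchmark-shaped table under the default study conditions."""
    return simulate_model_table(TableSimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
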