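import numpy as np
import pandas as pd
import pytest

from degbias import (
    SyntheticConfig,
    default_lexicon,
    make_truth,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_config():
    """A small synthetic world reused across read-only tests."""
    return SyntheticConfig(n_genes=300, n_diseases=2, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config)


@pytest.fixture(scope="session")
def toy_de_table():
    """Five genes with known p_adj/fc used by the filtering examples."""
    fc = np.array([2.5, 3.0, -2.2, 1.5, 0.5])
    log2fc = np.sign(fc) * np.log2(np.abs(fc))
    return pd.DataFrame(
        {
            "feature_id": [f"gene{i}" for i in range(1, 6)],
            "log2fc": log2fc,
            "fc": fc,
            "t_mod": np.sign(log2fc) * 3.0,
            "df_total": 10.0,
            "p": [0.001, 0.15, 0.001, 0.01, 0.001],
            "p_adj": [0.01, 0.2, 0.01, 0.04, 0.01],
        }
    )
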