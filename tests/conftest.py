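import numpy as np
import pytest

import bcrpqsar as bq


@pytest.fixture(scope="session")
def small_molecules():
    """60 standardized generator molecules, deterministic."""
    return bq.generate_molecules(bq.SyntheticSpec(n=60, seed=11))


@pytest.fixture(scope="session")
def bits_data():
    """Fast bits-only dataset with 3 planted causal features."""
    table, y, causal = bq.generate_bits_dataset(n=250, p=120, seed=7)
    return table, y, causal


@pytest.fixture(scope="session")
def rf_bits_model(bits_data):
    """Depth-limited random forest fit on the causal-bits dataset."""
    table, y, _ = bits_data
    return bq.fit("RF", {"n_estimators": 40, "max_depth": 5}, table, y,
                  seed=0)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small molecule dataset with activities and planted truth."""
    return bq.generate_dataset(bq.SyntheticSpec(n=120, seed=3))


def rng(seed=0):
    return np.random.default_rng(seed)
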