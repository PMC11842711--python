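import numpy as np
import pandas as pd
import pytest

from riverref import synthetic_catchments as sc


@pytest.fixture(scope="session")
def truth():
    return sc.TruthParams(seed=42)


@pytest.fixture(scope="session")
def catchments(truth):
    return sc.generate_catchments(300, truth, mdc_fraction=0.1)


@pytest.fixture()
def constant_discharge():
    return pd.DataFrame(
        {"date": pd.date_range("2010-01-01", periods=100, freq="D"), "flow": 1.0}
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
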