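import warnings

import numpy as np
import pandas as pd
import pytest

from fibpulse import generate_event


@pytest.fixture(scope="session")
def default_event():
    """One default 96-sample synthetic sampling event with ground truth."""
    return generate_event(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def grid_30min():
    return pd.date_range("2022-08-01 08:00", periods=96, freq="30min")


@pytest.fixture(autouse=True)
def _no_convergence_noise():
    """Silence benign small-sample warnings so real ones stand out."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield
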