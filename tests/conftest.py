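import numpy as np
import pandas as pd
import pytest

from ibdatlas import cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A small all-modality cohort shared by read-only tests."""
    cfg = cohort.CohortConfig(seed=42, n_patients=60)
    return cohort.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_npx_wide():
    """4 proteins x 6 samples with staggered missingness."""
    data = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [2.0, np.nan, 4.0, 5.0, np.nan, 7.0],
            [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
            [np.nan, np.nan, np.nan, 1.0, 2.0, 3.0],
        ]
    )
    return pd.DataFrame(
        data,
        index=[f"P{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
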