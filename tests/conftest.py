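import numpy as np
import pytest

from adct.pipeline import extract_features
from adct.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = SyntheticCohortConfig(n_nonresponse=8, n_response=14, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_feature_tables(small_cohort):
    return {
        "reader1": extract_features(small_cohort, "reader1"),
        "reader2": extract_features(small_cohort, "reader2"),
    }
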