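import numpy as np
import pytest

from mvhist import features, synthetic


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort configuration used across tests."""
    return synthetic.CohortConfig(
        n_patients=10, grid_shape=(16, 16, 8), seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    return features.build_feature_table(small_cohort.feature_inputs())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
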