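import numpy as np
import pytest

from tmsresp import SyntheticConfig, generate_cohort, cohort_features, FeatureConfig


def small_config(**overrides) -> SyntheticConfig:
    """A fast cohort for unit tests: 4+3 subjects, 6 channels, 30 s."""
    defaults = dict(n_pos=4, n_neg=3, n_channels=6, duration_s=30.0, seed=7)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_features(small_cohort):
    X, provenance, subject_ids = cohort_features(small_cohort, FeatureConfig())
    return X, provenance, subject_ids


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
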