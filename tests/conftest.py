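import pytest

from eggage import (
    SimConfig,
    build_feature_table,
    generate_dataset,
    strong_signal_config,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic colony: 24 years x 100 nests, realistic noise."""
    return generate_dataset(SimConfig(seed=101))


@pytest.fixture(scope="session")
def strong_dataset():
    """Low-noise colony with a pronounced concave age effect."""
    return generate_dataset(strong_signal_config(seed=202))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    nests, env = default_dataset
    return build_feature_table(nests, env, version="full", scheme="AGE2")


@pytest.fixture(scope="session")
def strong_features(strong_dataset):
    nests, env = strong_dataset
    return build_feature_table(nests, env, version="full", scheme="AGE2")
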