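import pytest
from hypothesis import settings

from nabh.ensemble import split_dataset, train_ensemble
from nabh.features import ScaleConfig, default_config
from nabh.synth import SyntheticSpec, build_labelled_dataset

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> ScaleConfig:
    return default_config()


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    # Reduced class sizes, same class structure as the full benchmark.
    return SyntheticSpec(n_pos=160, n_neg_albumin=60, n_neg_random=100, seed=7)


@pytest.fixture(scope="session")
def small_data(small_spec, config):
    return build_labelled_dataset(small_spec, config)


@pytest.fixture(scope="session")
def small_split(small_data):
    return split_dataset(small_data, 0.3, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_split, config):
    train, _ = small_split
    return train_ensemble(train, seed=7, scales_fingerprint=config.fingerprint())
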