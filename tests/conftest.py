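import pytest

from pulsechase.synthetic import GeneratorConfig, generate_raw_tables


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=20210426)


@pytest.fixture(scope="session")
def zero_noise_config():
    return GeneratorConfig(seed=20210426, sigma_block=0.0, sigma_mainplot=0.0,
                           sigma_resid=0.0, at_natural_jitter=0.0)


@pytest.fixture(scope="session")
def raw_bundle(default_config):
    """One default synthetic raw-data bundle, shared across tests."""
    return generate_raw_tables(default_config, dataset_index=0)


@pytest.fixture(scope="session")
def zero_noise_bundle(zero_noise_config):
    return generate_raw_tables(zero_noise_config, dataset_index=0)
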