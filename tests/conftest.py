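import pytest

from nomcea.params import default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def econ(config):
    return config.economics


@pytest.fixture(scope="session")
def strata(config):
    return config.age_strata
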