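import pytest

from pa_cea import DEFAULT_CONFIG, ModelConfig, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def end_cycle_config():
    """End-of-cycle reward convention (hand-computable single steps)."""
    return ModelConfig(reward_timing="end")
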