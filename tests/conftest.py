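import pytest

from rfacea import (
    AnalysisConfig,
    build_scenario,
    default_param_specs,
)


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def base_scenario(default_config):
    """Base-case scenario: printed monthly probabilities 0.0118 / 0.0251,
    costs 117.16 / 78.10 per month, utility 0.76, 5%/yr discount, 24 cycles."""
    return build_scenario(default_config)


@pytest.fixture(scope="session")
def param_table(default_config, base_scenario):
    """Sensitivity parameter table: 50%-200% ranges for probabilities and
    costs, published ranges for utilities, discount 0-5%."""
    return default_param_specs(default_config, base_scenario)
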