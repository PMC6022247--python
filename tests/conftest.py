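import pytest
from hypothesis import HealthCheck, settings

import dfucea

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_params():
    return dfucea.generate_base_case()


@pytest.fixture(scope="session")
def base_result(base_params):
    return dfucea.compare_strategies(base_params)


@pytest.fixture(scope="session")
def base_traces(base_params):
    return {
        name: dfucea.run_cohort(strat, base_params.shared)
        for name, strat in base_params.strategies.items()
    }
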