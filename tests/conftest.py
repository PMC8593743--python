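import pytest

from psorcea import (RewardConvention, build_strategies, builtin_base_case,
                     evaluate_arm)


@pytest.fixture(scope="session")
def base_config():
    return builtin_base_case()


@pytest.fixture(scope="session")
def base_results(base_config):
    """All eight arms evaluated under the calibrated default convention."""
    return [evaluate_arm(s, base_config, RewardConvention())
            for s in build_strategies(base_config)]


@pytest.fixture(scope="session")
def base_by_name(base_results):
    return {r.strategy.name: r for r in base_results}
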