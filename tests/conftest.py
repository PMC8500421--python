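import numpy as np
import pytest

from ribeval import ScenarioConfig, gen_mortality_index


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel: 15 locations x 8 years x 2 seasons."""
    return gen_mortality_index(ScenarioConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
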