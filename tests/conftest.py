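import numpy as np
import pytest

from singletonmap.expansion import DemeGrid, ExpansionScenario, make_habitat_map
from singletonmap.fixtures import demo_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo20():
    """20x20 homogeneous demo grid (land interior, sea border)."""
    return make_habitat_map("homogeneous", demo_grid(20))


@pytest.fixture(scope="session")
def demo_history(demo20):
    """A western-origin expansion history on the demo grid."""
    from singletonmap.expansion import run_forward_demography

    scenario = ExpansionScenario(
        origin=(3.5, 16.5), duration=250, n_loci=300, mutation_rate=2e-4
    )
    return run_forward_demography(demo20, scenario)
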