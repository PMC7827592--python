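import numpy as np
import pytest

from ampholyte.forcefield import ForceFieldParams
from ampholyte.synthetic import initial_configuration, make_scenario


@pytest.fixture(scope="session")
def ff_default() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture(scope="session")
def ff_ideal() -> ForceFieldParams:
    """Interactions off: Bjerrum length 0 and no excluded volume."""
    return ForceFieldParams(bjerrum_length=0.0, epsilon_wca=0.0)


@pytest.fixture(scope="session")
def small_system(ff_default):
    """One Lys5-Asp5 chain with salt at the reference concentrations."""
    sc = make_scenario("Lys5-Asp5", "KKKKKDDDDD", n_chains=1)
    topo = sc.build_topology()
    state = initial_configuration(sc, rng=42, ff=ff_default)
    return sc, topo, state


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
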