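import pytest

import terpfet as tf
from terpfet import simulate as sim


@pytest.fixture(scope="session")
def panel_and_ladder():
    return tf.load_panel()


@pytest.fixture(scope="session")
def panel(panel_and_ladder):
    return panel_and_ladder[0]


@pytest.fixture(scope="session")
def ladder(panel_and_ladder):
    return panel_and_ladder[1]


@pytest.fixture(scope="session")
def by_name(panel):
    return {a.name: a for a in panel}


@pytest.fixture()
def noiseless_config():
    return sim.default_config(seed=0, noise_rsd=0.0)


@pytest.fixture()
def default_config():
    return sim.default_config(seed=0)
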