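import numpy as np
import pytest

from hapsweep.coalescent import parse_ms_args
from hapsweep.synth import SweepPanelSpec, generate_sweep_panel

FST_CMD = (
    "./ms 422 1000 -t 91.4 -I 2 216 206 -m 1 2 3.2 -n 2 0.077 "
    "-en 0.0005 1 0.25 -en 0.001 2 0.077 -ej 0.00875 2 1 "
    "-en 0.0425 1 0.125 -r 5 8787"
)
ROH_CMD = (
    "./ms 422 1000 -t 750 -r 200 200000 -I 2 206 216 9 "
    "-en 0.0005 2 0.25 -en 0.001 1 0.077 -en 0.0425 2 0.125"
)


@pytest.fixture(scope="session")
def fst_model():
    return parse_ms_args(FST_CMD)


@pytest.fixture(scope="session")
def roh_model():
    return parse_ms_args(ROH_CMD)


@pytest.fixture(scope="session")
def default_panel():
    """One seeded default sweep panel with ground truth."""
    return generate_sweep_panel(SweepPanelSpec(seed=1))


@pytest.fixture()
def toy_rng():
    # function-scoped: every test sees an identical fresh stream
    return np.random.default_rng(12345)
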