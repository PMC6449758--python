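import numpy as np
import pytest

from boolcell import boolean_engine as be
from boolcell.tnf_model import build_cell_fate_network

FORK_BND = """
X { logic = X; rate_up = 0; rate_down = 0; }
A { logic = X AND NOT B; rate_up = 2; rate_down = 0; }
B { logic = X && !A; rate_up = 1; rate_down = 0; }
"""
FORK_CFG = """
X.is_input = TRUE;
X.istate = 1;
"""


@pytest.fixture(scope="session")
def fork_network() -> be.BooleanNetwork:
    """Two mutually exclusive targets racing at rates 2:1 behind one input."""
    return be.parse_network(FORK_BND, FORK_CFG)


@pytest.fixture(scope="session")
def cellfate_network() -> be.BooleanNetwork:
    return build_cell_fate_network()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
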