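import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

import phikit as pk


@pytest.fixture(scope="session")
def example_net():
    return pk.example_network()


@pytest.fixture(scope="session")
def example_sub(example_net):
    return pk.Subsystem(example_net, pk.EXAMPLE_STATE)


# Node indices of the example network, for readability.
A, B, C = 0, 1, 2
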