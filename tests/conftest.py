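import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pkdesign import EnergyModel, parse_dot_bracket


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hairpin():
    return parse_dot_bracket("(((...)))")


@pytest.fixture(scope="session")
def htype():
    return parse_dot_bracket("((..[[..))..]]")


def random_rna(rng, n, gc=0.5):
    bases = []
    for _ in range(n):
        if rng.random() < gc:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "U")
    return "".join(bases)
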