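import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mitocmp import CircularGenome, generate_ancestor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genome(length, seed, gid="g"):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return CircularGenome(gid, seq)


@pytest.fixture
def small_random():
    return random_genome(2000, 7)


@pytest.fixture
def ancestor_with_repeat():
    return generate_ancestor(50000, repeat_spec=[(2500, 2, "direct")], seed=1)
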