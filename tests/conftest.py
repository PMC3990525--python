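import numpy as np
import pytest

from fanseq.refindex import segment_reference
from fanseq.simulate import random_genome


@pytest.fixture(scope="session")
def small_genome():
    """20-kb random genome: long enough that 75-mers are unique w.h.p."""
    return random_genome(20_000, seed=11)


@pytest.fixture(scope="session")
def small_segments(small_genome):
    name, seq = small_genome
    return segment_reference({name: seq}, 50_000_000, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
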