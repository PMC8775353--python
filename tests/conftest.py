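import numpy as np
import pytest

from sectormut.records import ReferenceGenome
from sectormut.synthetic_data import random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_genome():
    return ReferenceGenome({"c1": "TTACGACGTT", "c2": "ACGTACGTACGTNNNN"})


@pytest.fixture
def random_ref(rng):
    return random_genome(rng, n_chrom=1, chrom_len=5_000)
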