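import numpy as np
import pytest

from evekit._seq import random_seq
from evekit.synthetic_data import DEFAULT_ANCHOR_MOTIFS, ElementSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_host():
    """3-contig host at 52% GC with a both/one/none telomere plan."""
    from evekit.synthetic_data import gen_host_genome

    return gen_host_genome(
        3, (60_000, 80_000), 0.52, "TTAGGG", ["both", "one", "none"], seed=11
    )


@pytest.fixture
def anchor_motifs():
    return list(DEFAULT_ANCHOR_MOTIFS)


@pytest.fixture
def tir_spec():
    return ElementSpec(20_290, 0.35, "TIR", 488, 5)


def random_dna(length, seed, gc=0.5):
    return random_seq(length, gc, np.random.default_rng(seed))
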