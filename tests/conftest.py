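import numpy as np
import pytest

from crmkit.io_formats import PFM
from crmkit.synthetic_data import SimConfig, muscle_motifs


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def motifs():
    return muscle_motifs()


@pytest.fixture
def simple_pfm():
    # strong consensus ACGTAC with small off-consensus counts
    counts = np.full((4, 6), 1.0)
    for j, b in enumerate("ACGTAC"):
        counts["ACGT".index(b), j] = 17.0
    return PFM("TEST1", "test-motif", counts)


@pytest.fixture
def small_config():
    return SimConfig(seed=11, genome_length=20_000, n_crm=8)


def random_sequence(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
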