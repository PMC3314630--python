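import numpy as np
import pytest

from gobiseq.genome_io import Feature, Replicon
from gobiseq.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_replicon(rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return Replicon(id="chr", sequence=seq)


@pytest.fixture
def small_features():
    return [
        Feature("chr", 100, 400, "+", "CDS", "g1", "protein one"),
        Feature("chr", 600, 1200, "-", "CDS", "g2", "protein two"),
        Feature("chr", 1500, 3000, "+", "rRNA", "rrn1", "16S"),
        Feature("chr", 3200, 3280, "+", "tRNA", "trn1", "tRNA-Ala"),
        Feature("chr", 3500, 4700, "+", "CDS", "g3", "protein three"),
    ]


@pytest.fixture
def sim_config():
    return SimConfig(seed=42)
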