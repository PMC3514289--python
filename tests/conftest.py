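import numpy as np
import pytest

from lakestream import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(20120)


@pytest.fixture
def small_cfg():
    """A scaled-down simulation configuration for fast unit tests."""
    return synth.SimConfig(
        seed=7,
        n_pops=3,
        n_ind=12,
        n_loci=4,
        alleles_per_locus=5,
        n_seq_per_pop=8,
        dloop_pops=("P1", "P2", "P3"),
        sites=(
            ("L1", "S1", "lake", 12),
            ("T1", "S1", "stream", 12),
            ("L2", "S2", "lake", 12),
            ("T2", "S2", "stream", 12),
        ),
    )
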