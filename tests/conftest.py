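import numpy as np
import pytest

from paleomito.seqs import random_genome
from paleomito.sim import PanelConfig, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def genome(rng):
    return random_genome(2000, rng)


@pytest.fixture
def clean_panel():
    """3 clades, 10 planted diffs each, no intra-clade noise."""
    return simulate_panel(
        PanelConfig(
            n_clades=3,
            samples_per_clade=4,
            genome_length=1500,
            planted_fixed_diffs_per_clade=10,
            intra_clade_mut_rate=0.0,
            seed=7,
        )
    )


@pytest.fixture
def noisy_panel():
    return simulate_panel(
        PanelConfig(
            n_clades=3,
            samples_per_clade=5,
            genome_length=1500,
            planted_fixed_diffs_per_clade=10,
            intra_clade_mut_rate=0.001,
            seed=11,
        )
    )
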