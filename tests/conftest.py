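import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from loopsim.fixtures import ToySystemSpec
from loopsim.genome import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spec():
    """Small 1 Mbp system with one convergent pair: fast to simulate."""
    return ToySystemSpec(
        chrom_lengths=(1_000_000,), n_pairs=1, pair_span=150_000,
        occupancy=0.9, puu=0.7, seed=7,
    )


@pytest.fixture
def fast_config():
    """Config scaled for speed: few cells, aggressive contact sampling."""
    return SimulationConfig(
        bin_size=10_000,
        diagonal_width=500_000,
        ncells=4,
        contact_sampling_fraction=0.25,
        seed=7,
    )
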