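import numpy as np
import pytest

from ldne.config import SimulationConfig
from ldne.maps import RecombinationMap
from ldne.simulate import HaplotypeSample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Tiny neutral scenario for fast structural checks."""
    length = 100_000
    return SimulationConfig(
        census_trajectory=((0, 50),),
        sequence_length_bp=length,
        mutation_rate=1e-6,
        recombination_map=RecombinationMap.uniform(length, 1.0),
        n_generations=10,
        sample_size=10,
        seed=7,
    )


def sample_from_haplotype_counts(n_ab, n_aB, n_Ab, n_AB, d_morgans=0.01,
                                 length_bp=1000):
    """Two-site haplotype sample with the given 2x2 table counts.

    Order: (0,0), (0,1), (1,0), (1,1) haplotype counts.
    """
    rows = ([(0, 0)] * n_ab + [(0, 1)] * n_aB + [(1, 0)] * n_Ab + [(1, 1)] * n_AB)
    mat = np.array(rows, dtype=np.uint8)
    return HaplotypeSample(mat, np.array([100, 200]),
                           np.array([0.0, d_morgans]), length_bp)
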