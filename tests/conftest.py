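import numpy as np
import pytest

from ssrevol.detect import DetectionConfig
from ssrevol.simulate import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def det_cfg():
    return DetectionConfig()


@pytest.fixture(scope="session")
def small_sim():
    """Two 30 kb chromosomes with 30 planted loci each."""
    cfg = SimulationConfig(seed=11, n_chromosomes=2, chromosome_length=30000,
                           planted_loci_per_chromosome=30)
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def library_sim():
    """Loci spaced widely enough that every flanked window is retained."""
    cfg = SimulationConfig(seed=13, n_chromosomes=2,
                           chromosome_length=100_000,
                           planted_loci_per_chromosome=110,
                           motif_length_weights={2: .2, 3: .2, 4: .2,
                                                 5: .2, 6: .2},
                           min_locus_spacing=720, te_per_chromosome=0)
    return generate_genome(cfg)


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
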