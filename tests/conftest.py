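import numpy as np
import pytest

from wolbshift import simdata


@pytest.fixture(scope="session")
def strain_pair():
    """Two 20 kb genomes at ~2% divergence, with realized distances."""
    cfg = simdata.SimStrainConfig(
        seed=11,
        genome_length=20_000,
        n_strains=2,
        target_distances=np.array([[0.0, 0.02], [0.02, 0.0]]),
    )
    return simdata.evolve_strains(cfg)


@pytest.fixture(scope="session")
def close_trio():
    """Three 20 kb genomes: A-B at 0.5%, both ~5% from C."""
    d = np.array(
        [
            [0.0, 0.005, 0.05],
            [0.005, 0.0, 0.05],
            [0.05, 0.05, 0.0],
        ]
    )
    cfg = simdata.SimStrainConfig(
        seed=7, genome_length=20_000, n_strains=3, target_distances=d
    )
    return simdata.evolve_strains(cfg)


@pytest.fixture(scope="session")
def random_genome():
    rng = np.random.default_rng(99)
    seq = simdata._codes_to_seq(rng.integers(0, 4, size=20_000, dtype=np.int8))
    return simdata.StrainGenome("random_bg", seq)
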