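import numpy as np
import pytest
from hypothesis import settings

from retromap import simulate as sim
from retromap.align import SeedIndex

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def provirus():
    return sim.make_provirus(seed=1)


@pytest.fixture(scope="session")
def small_genome(provirus):
    """100-kb single-chromosome genome with decoys at 0.95/0.90/0.85 identity."""
    genome, truth = sim.make_genome(
        1, [100_000], 0.42, [(0.95, 1), (0.90, 1), (0.85, 1)],
        provirus.ltr_seq, seed=7,
    )
    return genome, truth


@pytest.fixture(scope="session")
def planted(provirus):
    """60-kb decoy-free genome with one sense provirus planted at 30 kb."""
    genome, _ = sim.make_genome(1, [60_000], 0.45, [], provirus.ltr_seq, seed=5)
    site = sim.PlantedProvirus("chr1", 30_000, "S", 4)
    gmod, table = sim.plant_proviruses(genome, provirus, [site])
    return genome, gmod, table, site


@pytest.fixture(scope="session")
def planted_index(planted, provirus):
    genome, _, _, _ = planted
    return SeedIndex.from_genome(genome, provirus)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
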