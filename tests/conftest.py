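import numpy as np
import pytest

from ibdprio import pedsim
from ibdprio.genome import demo_genome


@pytest.fixture(scope="session")
def small_model():
    """Tiny genome for fast unit tests: 2 x 50 Mb autosomes + 50 Mb X."""
    return demo_genome(n_autosomes=2, autosome_mb=50, x_mb=50,
                       markers_per_mb=40)


@pytest.fixture(scope="session")
def demo_model():
    """The demo-scale genome used for expectation-level statistics."""
    return demo_genome()


@pytest.fixture(scope="session")
def sib_sim(demo_model):
    """One error-free sib-pair replicate at demo scale (shared, read-only)."""
    return pedsim.simulate_pedigree(pedsim.sib_pair_pedigree(), demo_model,
                                    seed=42)


@pytest.fixture(scope="session")
def family_sim(demo_model):
    """One error-free canonical two-family replicate (shared, read-only)."""
    spec = pedsim.canonical_two_family_pedigree()
    matrix, truth = pedsim.simulate_pedigree(spec, demo_model, seed=7)
    return spec, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
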