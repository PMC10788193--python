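import numpy as np
import pytest

from ednapop import LakeScenario, simulate_scenario, synthetic_panel


@pytest.fixture(scope="session")
def default_scenario():
    return LakeScenario(seed=11)


@pytest.fixture(scope="session")
def simulated(default_scenario):
    """One full synthetic dataset shared across read-only tests."""
    genotypes, counts, truth = simulate_scenario(default_scenario)
    return genotypes, counts, truth


@pytest.fixture(scope="session")
def small_panel():
    return synthetic_panel(n_snps=12, n_loci=10, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
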