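import numpy as np
import pytest

from panscreen import GenotypeMatrix, PhenotypeMatrix, SimConfig, simulate


@pytest.fixture
def small_genotype():
    return GenotypeMatrix.from_arrays(
        ["A", "B", "C"], ["f1", "f2"], [[1, 0], [2, 3], [1, 1]])


@pytest.fixture
def small_phenotype():
    return PhenotypeMatrix.from_arrays(
        ["A", "B", "C"], ["s1", "s2"], [[1, 0], [0, 1], [1, 1]])


@pytest.fixture
def sim_small():
    """A quick 12-species simulation with a couple of planted pairs."""
    config = SimConfig(n_species=12, n_families=40, n_substrates=6,
                       n_single_copy_core=10, n_planted=2,
                       n_degenerate_substrates=1, seed=7)
    return simulate(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
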