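import numpy as np
import pytest

from gxekit import data_io, simulate


@pytest.fixture(scope="session")
def small_geno():
    """60 individuals x 120 markers on 4 chromosomes."""
    return data_io.generate_synthetic_genotypes(60, 120, n_chrom=4, seed=101)


@pytest.fixture(scope="session")
def medium_geno():
    """150 individuals x 400 markers (shared across slower tests)."""
    return data_io.generate_synthetic_genotypes(150, 400, n_chrom=10, seed=202)


@pytest.fixture()
def sim_two_env(small_geno):
    """A two-environment simulation with moderate signal."""
    return simulate.simulate(small_geno, nqtn=10, h2=0.6, r=0.5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
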