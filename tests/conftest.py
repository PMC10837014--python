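import numpy as np
import pytest

from reactnorm import PhenotypeMatrix, default_scenario


@pytest.fixture
def tiny_pheno():
    """2 genotypes x 3 environments with hand-checkable means."""
    return PhenotypeMatrix(["g1", "g2"], ["A", "B", "C"],
                           np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]]))


@pytest.fixture(scope="session")
def scenario():
    """Default noisy synthetic study (64 lines x 200 markers, 9 environments)."""
    return default_scenario(seed=11)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Same shape with zero residual noise: estimates must be exact."""
    return default_scenario(seed=11, noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
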