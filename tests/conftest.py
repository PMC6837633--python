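import numpy as np
import pytest

from episwitch.circuit_models import Genotype, solution_k


@pytest.fixture(scope="session")
def bistable_center() -> Genotype:
    """The bistable solution genotype at the center of the bistable region:
    n_H = 16, K_D = 50, k chosen so A* = 20 is a fixed point (k* ~ 80)."""
    k_star, valid = solution_k(20.0, 16.0, 50.0)
    assert valid
    return Genotype(k_star, 16.0, 50.0)


@pytest.fixture(scope="session")
def constitutive() -> Genotype:
    """alpha = 1 removes regulation: a pure birth-death (M/M/inf) process."""
    return Genotype(k=20.0, n_H=1.0, K_D=10.0, alpha=1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
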