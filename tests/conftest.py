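import numpy as np
import pytest

from bindsim import EnergyMatrix, GeneratorConfig, random_energy_matrix


@pytest.fixture
def toy_m2():
    """m=2 matrix: eps(A,1)=0, eps(C,1)=1.5; eps(A,2)=0, eps(G,2)=0.7."""
    eps = np.zeros((4, 2))
    eps[1, 0] = 1.5   # C at position 1
    eps[2, 1] = 0.7   # G at position 2
    eps[2, 0] = 2.0
    eps[3, 0] = 2.5
    eps[1, 1] = 1.1
    eps[3, 1] = 3.0
    return EnergyMatrix(eps)


@pytest.fixture
def model_m3():
    """A fixed random m=3 model for exhaustive (64-sequence) checks."""
    return random_energy_matrix(GeneratorConfig(m=3, seed=11))


@pytest.fixture
def model_m8():
    """A fixed random default-scale (m=8) model."""
    return random_energy_matrix(GeneratorConfig(m=8, seed=42))
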