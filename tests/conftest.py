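import numpy as np
import pytest

from mepkit import ImagePath, RestraintSpec, ToySystem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def harmonic_1d():
    """Unit-mass 1-D harmonic oscillator, k=2, kT chosen so var = 0.298."""
    return ToySystem("harmonic_nd", dimension=1, parameters={"k": 2.0}, temperature=0.596)


@pytest.fixture
def muller_brown():
    return ToySystem("muller_brown", dimension=2, temperature=0.25, timestep=4e-5)


@pytest.fixture
def zigzag_path():
    return ImagePath([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])


@pytest.fixture
def restraint_at_origin():
    return RestraintSpec(center=[0.0], force_constant=10.0)
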