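import numpy as np
import pytest

from goalseq import LatticeSpec, NetworkParams, build_network
from goalseq.params import NeuronParams


@pytest.fixture(scope="session")
def net40():
    """Reduced-scale network (40x40 lattice over the full environment)."""
    return build_network(NetworkParams(lattice=LatticeSpec(grid_side=40)))


@pytest.fixture(scope="session")
def quiet_net():
    """Small noise-free network for deterministic integration checks."""
    p = NetworkParams(
        lattice=LatticeSpec(grid_side=10),
        ca3e=NeuronParams(t_refr=3.0, noise_sd=0.0),
        ca3i=NeuronParams(t_refr=4.0, noise_sd=0.0),
    )
    return build_network(p)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
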