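import numpy as np
import pytest

from arpnet import NetworkParams, SynapticWeights


@pytest.fixture
def small_params():
    """A small, fast network for unit tests."""
    return NetworkParams(N=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ring_oscillator():
    """Hand-built 4-neuron ring whose spontaneous attractor is a limit cycle.

    Each hidden unit drives its own output (forward), each output drives
    the next hidden unit (backward): activity rotates around the ring.
    """
    params = NetworkParams(N=4)
    N = 4
    J_ih = np.zeros((N, N))
    J_ho = 2.0 * np.eye(N)
    J_oh = np.zeros((N, N))
    for k in range(N):
        J_oh[(k + 1) % N, k] = 2.0
    return params, SynapticWeights(J_ih, J_ho, J_oh)


@pytest.fixture
def engineered_memory(small_params):
    """A network hand-wired to recall input 0 -> output 4 via hidden 2."""
    N = small_params.N
    J_ih = np.zeros((N, N))
    J_ho = np.zeros((N, N))
    J_oh = np.zeros((N, N))
    J_ih[2, 0] = 2.0
    J_ho[4, 2] = 2.0
    w = SynapticWeights(J_ih, J_ho, J_oh)
    inp = np.zeros(N)
    inp[0] = 1.0
    tgt = np.zeros(N)
    tgt[4] = 1.0
    return small_params, w, inp, tgt


def permute_all(w, perm):
    """Relabel neurons identically in every layer of a weight set."""
    return SynapticWeights(
        w.J_ih[np.ix_(perm, perm)],
        w.J_ho[np.ix_(perm, perm)],
        w.J_oh[np.ix_(perm, perm)],
    )
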