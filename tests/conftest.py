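import numpy as np
import pytest

from gtenet import (
    DriveParams,
    NeuronParams,
    SynapseParams,
    detect_bursts,
    generate_nonlocal,
    simulate,
    synthesize,
)
from gtenet.topology import DirectedNetwork


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_net():
    """Non-local ensemble network at reduced size for fast unit tests."""
    return generate_nonlocal(N=40, p=0.15, target_cc=0.3, seed=7)


@pytest.fixture(scope="session")
def empty_net():
    pos = np.random.default_rng(0).random((30, 2)) * 0.5
    return DirectedNetwork(np.zeros((30, 30), dtype=bool), pos, {})


@pytest.fixture(scope="session")
def bursting_run():
    """A 10-minute run of the default-regime culture model (N=100).

    Shared by every test that needs realistic bursting dynamics; the
    recurrent weight is the default-ensemble value that holds the burst
    rate near the 0.1 Hz target.
    """
    net = generate_nonlocal(N=100, p=0.12, target_cc=0.5, seed=1)
    spikes = simulate(net, syn=SynapseParams(g_int=5.35), duration=600.0, seed=11)
    return net, spikes


@pytest.fixture(scope="session")
def bursting_recording(bursting_run):
    net, spikes = bursting_run
    rec = synthesize(spikes, positions=net.positions, seed=21)
    return net, spikes, rec
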