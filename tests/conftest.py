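import numpy as np
import pytest

from fcthresh.simulator import SpikeTrainSet


@pytest.fixture(scope="session")
def rnd_net():
    from fcthresh.topologies import generate_random

    return generate_random(seed=11)


@pytest.fixture(scope="session")
def small_rnd_spikes():
    """A short simulation of a small random network, shared across tests."""
    from fcthresh.simulator import SimulationConfig, run_network
    from fcthresh.topologies import generate_random

    net = generate_random(n_neurons=60, n_excitatory=48, out_degree=12, seed=3)
    cfg = SimulationConfig(duration_s=60.0, stdp_freeze_s=20.0, seed=4)
    return net, run_network(net, cfg)


def poisson_trains(n_neurons, rate_hz, duration_ms, seed=0):
    """Independent homogeneous Poisson spike trains."""
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for i in range(n_neurons):
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        ids.append(np.full(n, i))
        times.append(np.sort(rng.uniform(0.0, duration_ms, n)))
    return SpikeTrainSet(
        np.concatenate(ids), np.concatenate(times), n_neurons, duration_ms
    )
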