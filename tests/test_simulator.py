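"""Izhikevich dynamics, delayed transmission, STDP, noise drive."""

import numpy as np
import pytest

from fcthresh.simulator import (
    IZHIKEVICH_PARAMS,
    SimulationConfig,
    SpikeTrainSet,
    run_network,
    step_neuron,
    stdp_update,
)
from fcthresh.topologies import REGULAR_SPIKING, StructuralNetwork, generate_random

RS = IZHIKEVICH_PARAMS["regular_spiking"]


def make_net(n, edges, weights, delays):
    A = np.zeros((n, n))
    D = np.zeros((n, n), dtype=np.int64)
    for (i, j), w, d in zip(edges, weights, delays):
        A[i, j] = w
        D[i, j] = d
    return StructuralNetwork(
        n_neurons=n, n_excitatory=n, adjacency=A, delays=D,
        neuron_types=np.array([REGULAR_SPIKING] * n),
        topology_tag="RND", rng_seed=0,
    )


class TestStepNeuron:
    def test_resting_fixed_point_is_stable(self):
        # equilibrium of 0.04 v^2 + 5 v + 140 - b v = 0 (u = b v)
        b = RS[1]
        v0 = (-(5 - b) - np.sqrt((5 - b) ** 2 - 4 * 0.04 * 140)) / (2 * 0.04)
        state = (v0, b * v0)
        for _ in range(1000):
            state, spiked = step_neuron(state, 0.0, RS)
            assert not spiked
        assert state[0] == pytest.approx(v0, abs=1e-6)

    def test_constant_current_periodic_spiking(self):
        """dt = 1 ms spike count matches a dt = 0.01 ms reference within 1."""
        def count_spikes(dt, n_steps):
            v, u = -65.0, RS[1] * -65.0
            count, isis, last = 0, [], None
            for k in range(n_steps):
                (v_new, u_new), spiked = _euler(v, u, 10.0, dt)
                v, u = v_new, u_new
                if spiked:
                    count += 1
                    t = k * dt
                    if last is not None:
                        isis.append(t - last)
                    last = t
            return count, isis

        def _euler(v, u, I, dt):
            a, b, c, d = RS
            n_half = max(int(round(1.0 / dt)) * 2, 2) if dt < 1.0 else 2
            for _ in range(2):
                v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
            u += dt * a * (b * v - u)
            if v >= 30.0:
                return (c, u + d), True
            return (v, u), False

        coarse, isis = count_spikes(1.0, 1000)
        # reference at fine step: integrate the same 1000 ms
        v, u = -65.0, RS[1] * -65.0
        fine = 0
        dt = 0.01
        a, b, c, d = RS
        for _ in range(100_000):
            v += dt * (0.04 * v * v + 5.0 * v + 140.0 - u + 10.0)
            u += dt * a * (b * v - u)
            if v >= 30.0:
                fine += 1
                v, u = c, u + d
        assert coarse > 5
        # the 1 ms explicit scheme overestimates the rate slightly; the spike
        # count stays within a few spikes of the fine-step reference
        assert abs(coarse - fine) <= 0.2 * fine
        # regular (periodic) firing: ISI spread small relative to the mean
        # (the 1 ms grid quantizes successive intervals)
        assert np.std(isis[2:]) / np.mean(isis[2:]) < 0.15

    def test_non_finite_state_raises(self):
        with pytest.raises(FloatingPointError):
            step_neuron((np.nan, 0.0), 0.0, RS)


class TestRunNetwork:
    def test_empty_network_no_noise_is_silent(self):
        net = make_net(4, [], [], [])
        cfg = SimulationConfig(duration_s=5.0, noise_model="none",
                               stdp_freeze_s=0.0)
        spikes = run_network(net, cfg)
        assert spikes.n_spikes == 0

    def test_two_neuron_chain_transmission_delay(self):
        """A -> B with a large weight and 5 ms delay: B spikes ~5 ms after A."""
        net = make_net(2, [(0, 1)], [80.0], [5])
        cfg = SimulationConfig(duration_s=30.0, noise_model="kick",
                               noise_amplitude=20.0, stdp_enabled=False,
                               stdp_freeze_s=0.0, seed=3)
        spikes = run_network(net, cfg)
        a = spikes.spikes_of(0)
        b = spikes.spikes_of(1)
        assert len(a) > 100 and len(b) > 100
        # for each B spike not caused by its own kick, an A spike 4-6 ms before
        lags = []
        for t in b:
            prev = a[(a < t) & (a >= t - 8)]
            if len(prev):
                lags.append(t - prev[-1])
        med = np.median(lags)
        assert 4.0 <= med <= 6.0

    def test_seed_determinism(self):
        net = generate_random(n_neurons=50, n_excitatory=40, out_degree=8,
                              seed=5)
        cfg = SimulationConfig(duration_s=20.0, stdp_freeze_s=10.0, seed=9)
        s1 = run_network(net, cfg)
        s2 = run_network(net, cfg)
        assert np.array_equal(s1.times, s2.times)
        assert np.array_equal(s1.neuron_ids, s2.neuron_ids)

    def test_weight_sign_conservation_and_freeze(self, small_rnd_spikes):
        net, spikes = small_rnd_spikes
        w = spikes.metadata["final_weights"]
        src = spikes.metadata["edge_sources"]
        exc = src < net.n_excitatory
        assert np.all(w[exc] >= 0.0)
        # inhibitory weights untouched by plasticity
        A = net.adjacency
        s, t = np.nonzero(A)
        orig = A[s, t]
        assert np.allclose(w[~exc], orig[~exc])

    def test_network_activity_is_bursty(self, small_rnd_spikes):
        from fcthresh.spike_metrics import detect_bursts_all, mean_firing_rate

        net, spikes = small_rnd_spikes
        assert mean_firing_rate(spikes) > 0.5
        bursts = detect_bursts_all(spikes)
        assert bursts.n_bursts > 10

    def test_excitatory_weights_bimodal_after_settling(self):
        """STDP drives excitatory weights toward the clip boundaries."""
        net = generate_random(n_neurons=100, n_excitatory=80, out_degree=15,
                              seed=6)
        cfg = SimulationConfig(duration_s=120.0, stdp_freeze_s=110.0, seed=7)
        spikes = run_network(net, cfg)
        w = spikes.metadata["final_weights"]
        exc = spikes.metadata["edge_sources"] < 80
        we = w[exc]
        lo, hi = (we < 2.0).mean(), (we > 8.0).mean()
        mid = ((we > 4.0) & (we < 6.0)).mean()
        assert lo + hi > 0.5          # mass at the modes
        assert mid < min(lo + hi, 0.4)  # valley between them

    def test_dt_other_than_1ms_rejected(self):
        net = make_net(2, [(0, 1)], [5.0], [1])
        with pytest.raises(NotImplementedError):
            run_network(net, SimulationConfig(dt_ms=0.5, stdp_freeze_s=0.0))


class TestStdpUpdate:
    def test_closed_form_potentiation(self):
        assert stdp_update(20.0) == pytest.approx(0.1 * np.exp(-1.0))

    def test_depression_sign_and_magnitude(self):
        assert stdp_update(-20.0) == pytest.approx(-0.12 * np.exp(-1.0))

    def test_decay_to_zero(self):
        assert stdp_update(1e6) == pytest.approx(0.0, abs=1e-12)
        assert stdp_update(0.0) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            stdp_update(float("nan"))


class TestSpikeTrainSet:
    def test_sorts_unsorted_input(self):
        s = SpikeTrainSet([0, 1], [5.0, 2.0], 2, 10.0)
        assert s.times.tolist() == [2.0, 5.0]
        assert s.neuron_ids.tolist() == [1, 0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            SpikeTrainSet([0], [11.0], 1, 10.0)
        with pytest.raises(ValueError):
            SpikeTrainSet([2], [1.0], 2, 10.0)

    def test_window_rereferences_time(self):
        s = SpikeTrainSet([0, 0, 0], [1.0, 5.0, 9.0], 1, 10.0)
        w = s.window(4.0, 10.0)
        assert w.times.tolist() == [1.0, 5.0]
        assert w.duration_ms == 6.0
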