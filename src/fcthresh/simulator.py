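"""Spiking-network simulator: Izhikevich neurons, conduction delays, STDP.

The membrane dynamics follow the two-variable quadratic integrate model

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)
    if v >= 30 mV: v <- c, u <- u + d

integrated with a 1 ms Euler step (the voltage equation in two 0.5 ms
half-steps for stability, following the reference implementation of the
model).  Regular-spiking parameters (a=0.02, b=0.2, c=-65, d=8) are used for
excitatory neurons and fast-spiking parameters (a=0.1, b=0.2, c=-65, d=8) for
inhibitory ones.

Synaptic transmission is a pure conduction delay: a spike of neuron i at time
t adds weight w_ij to the input current of neuron j at time t + delay_ij.
Excitatory weights are plastic under spike-timing-dependent plasticity with
exponential windows (potentiation A+ e^{-t/tau+}, depression A- e^{-t/tau-},
nearest-spike pairing on delay-corrected lags) until ``stdp_freeze_s``, after
which all weights are frozen.  Inhibitory weights are never plastic.

Spontaneous activity is driven by noise; the default model injects a fixed
current kick (amplitude 20) into one uniformly chosen neuron per millisecond,
the convention of the reference delayed-STDP network model.  A per-neuron
Gaussian current mode is also available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "IZHIKEVICH_PARAMS",
    "SimulationConfig",
    "SpikeTrainSet",
    "step_neuron",
    "stdp_update",
    "run_network",
]

#: per-type Izhikevich parameters (a, b, c, d)
IZHIKEVICH_PARAMS = {
    "regular_spiking": (0.02, 0.2, -65.0, 8.0),
    "fast_spiking": (0.1, 0.2, -65.0, 8.0),
}

SPIKE_THRESHOLD = 30.0  # mV


@dataclass
class SimulationConfig:
    """Simulation parameters; defaults reproduce the benchmark conditions."""

    duration_s: float = 900.0
    dt_ms: float = 1.0
    stdp_tau_plus: float = 20.0
    stdp_tau_minus: float = 20.0
    stdp_A_plus: float = 0.1
    stdp_A_minus: float = 0.12
    stdp_freeze_s: float = 300.0
    stdp_enabled: bool = True
    w_max: float = 10.0
    noise_model: str = "kick"  # "kick" | "gaussian" | "none"
    noise_amplitude: float = 20.0
    noise_rate: float = 1.0  # expected kicks per ms (kick mode)
    noise_sigma: float = 5.0
    seed: int = 0
    izhikevich_params: dict = field(
        default_factory=lambda: dict(IZHIKEVICH_PARAMS)
    )

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.stdp_freeze_s > self.duration_s:
            raise ValueError("stdp_freeze_s must not exceed duration_s")
        if self.stdp_A_plus <= 0 or self.stdp_A_minus <= 0:
            raise ValueError("STDP amplitudes must be positive")
        if self.noise_model not in ("kick", "gaussian", "none"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SpikeTrainSet:
    """Spike events (neuron id, time in ms), sorted by time."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration_ms: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size:
            if self.times.min() < 0 or self.times.max() > self.duration_ms:
                raise ValueError("spike times outside [0, duration]")
            if self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n_neurons:
                raise ValueError("neuron ids outside [0, n_neurons)")
            if np.any(np.diff(self.times) < 0):
                order = np.argsort(self.times, kind="stable")
                self.neuron_ids = self.neuron_ids[order]
                self.times = self.times[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def window(self, t0_ms: float, t1_ms: float) -> "SpikeTrainSet":
        """Sub-recording on [t0, t1), re-referenced to start at 0 ms."""
        keep = (self.times >= t0_ms) & (self.times < t1_ms)
        return SpikeTrainSet(
            self.neuron_ids[keep],
            self.times[keep] - t0_ms,
            self.n_neurons,
            t1_ms - t0_ms,
            dict(self.metadata, window=(t0_ms, t1_ms)),
        )


def step_neuron(state, input_current, params, dt=1.0):
    """Single Euler step of one Izhikevich neuron.

    Returns ``((v, u), spiked)``.  The voltage equation is advanced in two
    half-steps; on threshold crossing the membrane is reset before the next
    integration step.
    """
    v, u = state
    a, b, c, d = params
    if not (np.isfinite(v) and np.isfinite(u) and np.isfinite(input_current)):
        raise FloatingPointError("non-finite neuron state or input")
    for _ in range(2):
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + input_current)
    u += dt * params[0] * (b * v - u)
    spiked = v >= SPIKE_THRESHOLD
    if spiked:
        v, u = c, u + d
    return (v, u), bool(spiked)


def stdp_update(dt_ms, A_plus=0.1, A_minus=0.12, tau_plus=20.0, tau_minus=20.0):
    """STDP weight change for a pre/post lag.

    ``dt_ms`` > 0 (pre before post) potentiates by ``A_plus * exp(-dt/tau+)``;
    ``dt_ms`` < 0 depresses by ``A_minus * exp(-|dt|/tau-)``.  A coincident
    pair (dt = 0) produces no change.
    """
    dt_ms = float(dt_ms)
    if not np.isfinite(dt_ms):
        raise ValueError("timing difference must be finite")
    if dt_ms > 0:
        return A_plus * np.exp(-dt_ms / tau_plus)
    if dt_ms < 0:
        return -A_minus * np.exp(dt_ms / tau_minus)
    return 0.0


@njit(cache=True)
def _simulate(
    n_steps,
    v,
    u,
    a,
    b,
    c,
    d,
    out_indptr,
    out_targets,
    out_delays,
    w,
    w_is_exc,
    in_indptr,
    in_sources,
    in_edges,
    in_delays,
    max_delay,
    noise_mode,  # 0 none, 1 kick, 2 gaussian
    noise_amp,
    noise_rate,
    noise_sigma,
    stdp_on,
    freeze_step,
    A_plus,
    A_minus,
    tau_plus,
    tau_minus,
    w_max,
    seed,
    spike_n,
    spike_t,
):
    np.random.seed(seed)
    n = v.shape[0]
    nslots = max_delay + 1
    Ibuf = np.zeros((nslots, n))
    last_fire = np.full(n, -1.0e18)
    count = 0
    cap = spike_n.shape[0]
    for t in range(n_steps):
        slot = t % nslots
        I = Ibuf[slot].copy()
        Ibuf[slot, :] = 0.0
        if noise_mode == 1:
            kicks = int(noise_rate)
            if noise_rate - kicks > 0.0 and np.random.random() < noise_rate - kicks:
                kicks += 1
            for _ in range(kicks):
                I[np.random.randint(n)] += noise_amp
        elif noise_mode == 2:
            for i in range(n):
                I[i] += noise_sigma * np.random.randn()
        plastic = stdp_on and t < freeze_step
        for i in range(n):
            vi = v[i]
            ui = u[i]
            Ii = I[i]
            vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + Ii)
            vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + Ii)
            ui += a[i] * (b[i] * vi - ui)
            if vi >= 30.0:
                if count >= cap:
                    return -1, t
                spike_n[count] = i
                spike_t[count] = t
                count += 1
                # potentiation: incoming excitatory synapses whose last
                # presynaptic spike arrived before this postsynaptic spike
                if plastic:
                    for e in range(in_indptr[i], in_indptr[i + 1]):
                        src = in_sources[e]
                        eid = in_edges[e]
                        if w_is_exc[eid]:
                            arr = last_fire[src] + in_delays[e]
                            lag = t - arr
                            if 0.0 < lag < 10.0 * tau_plus:
                                nw = w[eid] + A_plus * np.exp(-lag / tau_plus)
                                w[eid] = nw if nw < w_max else w_max
                # schedule delayed delivery; depression of outgoing excitatory
                # synapses whose target fired less than a delay ago
                for e in range(out_indptr[i], out_indptr[i + 1]):
                    tgt = out_targets[e]
                    dly = out_delays[e]
                    Ibuf[(t + dly) % nslots, tgt] += w[e]
                    if plastic and w_is_exc[e]:
                        lag = (t + dly) - last_fire[tgt]
                        if 0.0 < lag < 10.0 * tau_minus:
                            nw = w[e] - A_minus * np.exp(-lag / tau_minus)
                            w[e] = nw if nw > 0.0 else 0.0
                last_fire[i] = t
                vi = c[i]
                ui = ui + d[i]
            elif vi != vi:  # NaN guard
                return -2, t
            v[i] = vi
            u[i] = ui
    return count, n_steps


def _csr_from_network(net):
    """Edge-list CSR views (by source and by target) of a StructuralNetwork."""
    A = net.adjacency
    src, tgt = np.nonzero(A)
    order = np.lexsort((tgt, src))
    src, tgt = src[order], tgt[order]
    w = A[src, tgt].copy()
    dly = net.delays[src, tgt].astype(np.int64)
    n = net.n_neurons
    out_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_indptr[1:], src, 1)
    out_indptr = np.cumsum(out_indptr)
    # incoming view: edges sorted by target
    in_order = np.lexsort((src, tgt))
    in_sources = src[in_order]
    in_edges = np.arange(len(src))[in_order]
    in_delays = dly[in_order]
    in_indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(in_indptr[1:], tgt[in_order], 1)
    in_indptr = np.cumsum(in_indptr)
    return out_indptr, tgt, dly, w, in_indptr, in_sources, in_edges, in_delays, src


def run_network(net, cfg: SimulationConfig | None = None) -> SpikeTrainSet:
    """Simulate spontaneous activity of a structural network.

    Returns the emitted spike trains; ``net.adjacency`` is left untouched (the
    plastic weights evolve on an internal copy, available in the result
    metadata as ``final_weights_digest``).
    """
    if cfg is None:
        cfg = SimulationConfig()
    if cfg.dt_ms != 1.0:
        raise NotImplementedError(
            "the network integrator uses a fixed 1 ms step "
            "(two 0.5 ms half-steps for the voltage equation)"
        )
    n = net.n_neurons
    n_steps = int(round(cfg.duration_s * 1000.0 / cfg.dt_ms))
    (out_indptr, out_targets, out_delays, w, in_indptr, in_sources,
     in_edges, in_delays, edge_src) = _csr_from_network(net)
    w_is_exc = (edge_src < net.n_excitatory)

    params = np.array(
        [cfg.izhikevich_params[t] for t in net.neuron_types], dtype=np.float64
    ).reshape(n, 4) if n else np.zeros((0, 4))
    a, b, c, d = (params[:, k].copy() for k in range(4))
    v = np.full(n, -65.0)
    u = b * v

    noise_mode = {"none": 0, "kick": 1, "gaussian": 2}[cfg.noise_model]
    freeze_step = int(round(cfg.stdp_freeze_s * 1000.0 / cfg.dt_ms))
    max_delay = int(out_delays.max()) if len(out_delays) else 1

    cap = max(int(n * n_steps * 0.03), 100_000)
    spike_n = np.empty(cap, dtype=np.int64)
    spike_t = np.empty(cap, dtype=np.float64)
    count, stop = _simulate(
        n_steps, v, u, a, b, c, d,
        out_indptr, out_targets, out_delays, w, w_is_exc,
        in_indptr, in_sources, in_edges, in_delays, max_delay,
        noise_mode, float(cfg.noise_amplitude), float(cfg.noise_rate),
        float(cfg.noise_sigma),
        bool(cfg.stdp_enabled), freeze_step,
        float(cfg.stdp_A_plus), float(cfg.stdp_A_minus),
        float(cfg.stdp_tau_plus), float(cfg.stdp_tau_minus),
        float(cfg.w_max), int(cfg.seed) & 0x7FFFFFFF,
        spike_n, spike_t,
    )
    if count == -1:
        raise RuntimeError(
            f"spike buffer overflow at t = {stop} ms: network activity "
            "exceeds 30 spikes/s/neuron on average (runaway excitation?)"
        )
    if count == -2:
        raise FloatingPointError(
            f"non-finite membrane potential at t = {stop} ms"
        )
    return SpikeTrainSet(
        spike_n[:count].copy(),
        spike_t[:count].copy(),
        n_neurons=n,
        duration_ms=n_steps * cfg.dt_ms,
        metadata={
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "topology_tag": net.topology_tag,
            "network_seed": net.rng_seed,
            "noise_model": cfg.noise_model,
            "noise_amplitude": cfg.noise_amplitude
            if cfg.noise_model == "kick" else cfg.noise_sigma,
            "final_weights": w,
            "edge_sources": edge_src,
            "edge_targets": out_targets,
        },
    )
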