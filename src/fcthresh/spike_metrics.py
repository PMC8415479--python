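"""First-order spiking/bursting statistics: MFR, burst detection, MBR, BD.

A burst is a run of three or more temporally packed spikes (consecutive
inter-spike intervals at most ``max_isi_ms``) followed by a quiescent period
longer than ``quiescence_ms`` (string-method convention; defaults 100 ms for
both).  A qualifying run at the end of the recording counts as a burst even
without a trailing quiescent period, to avoid censoring bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Burst",
    "BurstSet",
    "mean_firing_rate",
    "detect_bursts",
    "detect_bursts_all",
    "mean_bursting_rate",
    "burst_duration",
]


@dataclass
class Burst:
    start_ms: float
    end_ms: float
    n_spikes: int


@dataclass
class BurstSet:
    """Per-neuron burst lists."""

    bursts: dict[int, list[Burst]] = field(default_factory=dict)
    n_neurons: int = 0

    @property
    def n_bursts(self) -> int:
        return sum(len(b) for b in self.bursts.values())

    def all_bursts(self) -> list[Burst]:
        return [b for lst in self.bursts.values() for b in lst]


def mean_firing_rate(spikes) -> float:
    """Spikes per second averaged over the neurons: total / duration / N."""
    if spikes.duration_ms <= 0:
        raise ValueError("duration must be positive")
    return spikes.n_spikes / spikes.duration_s / spikes.n_neurons


def detect_bursts(
    spike_times,
    min_spikes: int = 3,
    max_isi_ms: float = 100.0,
    quiescence_ms: float = 100.0,
) -> list[Burst]:
    """Bursts of one spike train (sorted times, ms).

    Maximal runs with consecutive ISIs <= ``max_isi_ms`` qualify when they
    contain >= ``min_spikes`` spikes and are followed by a gap >
    ``quiescence_ms`` (or by the end of the recording).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted ascending")
    bursts: list[Burst] = []
    if t.size == 0:
        return bursts
    run_start = 0
    for k in range(1, t.size + 1):
        end_of_run = k == t.size or (t[k] - t[k - 1]) > max_isi_ms
        if end_of_run:
            n = k - run_start
            if n >= min_spikes:
                gap_ok = k == t.size or (t[k] - t[k - 1]) > quiescence_ms
                if gap_ok:
                    bursts.append(Burst(float(t[run_start]), float(t[k - 1]), n))
            run_start = k
    return bursts


def detect_bursts_all(spikes, **kwargs) -> BurstSet:
    """Per-neuron burst detection over a SpikeTrainSet."""
    out = BurstSet(n_neurons=spikes.n_neurons)
    for i in range(spikes.n_neurons):
        b = detect_bursts(spikes.spikes_of(i), **kwargs)
        if b:
            out.bursts[i] = b
    return out


def mean_bursting_rate(burst_set: BurstSet, duration_s: float) -> float:
    """Bursts per minute averaged over the neurons."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if burst_set.n_neurons == 0:
        return 0.0
    return burst_set.n_bursts / (duration_s / 60.0) / burst_set.n_neurons


def burst_duration(burst_set: BurstSet) -> float:
    """Mean burst duration (ms) over all detected bursts; NaN when none."""
    bursts = burst_set.all_bursts()
    if not bursts:
        return float("nan")
    return float(np.mean([b.end_ms - b.start_ms for b in bursts]))
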