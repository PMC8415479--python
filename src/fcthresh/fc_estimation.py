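"""Signed functional connectivity estimation from spike trains.

The default estimator is a baseline-corrected delayed cross-correlogram: for
every ordered pair (i, j) the spike trains are binned (1 ms) and the
cross-correlogram counts C_l = sum_t x_i(t) x_j(t + l) are computed for lags
|l| <= 2 * delay_window.  A per-lag baseline is the hollow local average of
the correlogram (the mean over the surrounding +-12 lags with the central
+-2 core excluded).  This local predictor absorbs the slow, broad
co-modulation that network bursts impose on all lags, while a monosynaptic
connection appears as a sharp excess (excitation) or a brief deficit
(inhibition) at positive lags 1..delay_window, where i leads j.  The summary
value is the dominant signed deviation from the baseline, normalized by the
geometric mean of the two spike counts so values are comparable across
firing-rate differences:

    CM(i -> j) = +(max_l C_l - baseline) / sqrt(n_i n_j)   (excess dominant)
                 -(baseline - min_l C_l) / sqrt(n_i n_j)   (deficit dominant)

Lag 0 is excluded (no direction can be assigned).  Statistically independent
trains score near zero; the matrix has an exactly zero diagonal, and silent
neurons produce zero rows/columns.

The estimator front-end is exchangeable: any function producing a signed CM
from a SpikeTrainSet (e.g., a TSPE implementation) can be used by the
thresholding stage, which only requires a signed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

__all__ = [
    "ConnectivityMatrix",
    "estimate_cm",
    "estimate_pair",
    "shuffle_train",
]


@dataclass
class ConnectivityMatrix:
    values: np.ndarray
    estimator_tag: str = "delayed-xcorr"
    delay_window: float = 25.0
    bin_ms: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix must be finite")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def _binned_counts(spikes, bin_ms):
    n_bins = int(np.ceil(spikes.duration_ms / bin_ms))
    n_bins = max(n_bins, 1)
    b = np.minimum((spikes.times / bin_ms).astype(np.int64), n_bins - 1)
    data = np.ones(len(b), dtype=np.float32)
    S = csr_matrix(
        (data, (spikes.neuron_ids, b)), shape=(spikes.n_neurons, n_bins)
    )
    S.sum_duplicates()
    return S, n_bins


def _ccg_stack(SA, SB, L, self_pair=False):
    """Cross-correlogram count stack over lags -L..L.

    ``ccg[L + l][i, j] = sum_t a_i(t) b_j(t + l)`` for row sets A (leading)
    and B (following).  When ``self_pair`` (A is B), negative lags are filled
    by transposition instead of extra products.
    """
    nA, nB = SA.shape[0], SB.shape[0]
    SBT = SB.T.tocsr()
    SAT = SA.T.tocsr()
    ccg = np.empty((2 * L + 1, nA, nB), dtype=np.float32)
    for lag in range(L + 1):
        prod = (SA @ SBT) if lag == 0 else (SA[:, :-lag] @ SBT[lag:])
        ccg[L + lag] = prod.toarray()
        if lag > 0:
            if self_pair:
                ccg[L - lag] = ccg[L + lag].T
            else:
                ccg[L - lag] = (SB[:, :-lag] @ SAT[lag:]).toarray().T
    return ccg


#: hollow-average predictor windows (lags): outer span and excluded core
_PREDICTOR_OUTER = 25
_PREDICTOR_CORE = 5


def _hollow_baseline(ccg):
    """Per-lag local baseline: mean of the surrounding lags within the outer
    window, the central core excluded ("partially hollow" smoother)."""
    from scipy.ndimage import uniform_filter1d

    outer = uniform_filter1d(ccg, _PREDICTOR_OUTER, axis=0, mode="nearest")
    core = uniform_filter1d(ccg, _PREDICTOR_CORE, axis=0, mode="nearest")
    return (_PREDICTOR_OUTER * outer - _PREDICTOR_CORE * core) / (
        _PREDICTOR_OUTER - _PREDICTOR_CORE
    )


def _signed_deviation(ccg, L, W, mode="signed"):
    """Deviation of the causal lags 1..W from the hollow local baseline.

    mode="signed": the dominant deviation, positive for an excess (putative
    excitation), negative for a deficit (putative inhibition).
    mode="excitation": the excess only — appropriate for networks known to
    carry no inhibitory population, where deficits are pure noise.
    """
    resid = ccg - _hollow_baseline(ccg)
    causal = resid[L + 1 : L + W + 1]
    excess = causal.max(axis=0)
    if mode == "excitation":
        return excess
    deficit = -causal.min(axis=0)
    return np.where(excess >= deficit, excess, -deficit)


def estimate_cm(
    spikes,
    delay_window: float = 25.0,
    bin_ms: float = 1.0,
    mode: str = "signed",
) -> ConnectivityMatrix:
    """Estimate the full signed N x N connectivity matrix (see module docs).

    ``mode="excitation"`` scores only correlogram excesses (for purely
    excitatory networks); the default "signed" discriminates excitatory and
    inhibitory connections by the sign of the dominant deviation.
    """
    if mode not in ("signed", "excitation"):
        raise ValueError("mode must be 'signed' or 'excitation'")
    n = spikes.n_neurons
    if n < 2:
        raise ValueError("connectivity estimation requires >= 2 neurons")
    if spikes.n_spikes == 0:
        raise ValueError("cannot estimate connectivity from an empty spike set")
    W = int(round(delay_window / bin_ms))
    L = 2 * W  # correlogram support used for the baseline
    S, n_bins = _binned_counts(spikes, bin_ms)
    if L >= n_bins:
        raise ValueError("recording too short for the requested delay window")

    counts = np.asarray(S.sum(axis=1)).ravel()
    silent = counts == 0
    if silent.any():
        warnings.warn(
            f"{int(silent.sum())} silent neuron(s): rows/columns set to 0"
        )

    ccg = _ccg_stack(S, S, L, self_pair=True)
    signed = _signed_deviation(ccg, L, W, mode=mode)
    norm = np.sqrt(np.outer(counts, counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(norm > 0, signed / norm, 0.0)
    np.fill_diagonal(values, 0.0)
    values[silent, :] = 0.0
    values[:, silent] = 0.0
    return ConnectivityMatrix(
        values=values.astype(np.float64),
        estimator_tag=f"delayed-xcorr-{mode}",
        delay_window=delay_window,
        bin_ms=bin_ms,
        provenance={
            "n_neurons": n,
            "n_spikes": spikes.n_spikes,
            "duration_ms": spikes.duration_ms,
            **{k: v for k, v in spikes.metadata.items()
               if isinstance(v, (str, int, float))},
        },
    )


def cross_values(spikes_a, spikes_b, delay_window: float = 25.0,
                 bin_ms: float = 1.0) -> np.ndarray:
    """Estimator values between two spike sets: entry (i, j) treats train i of
    ``spikes_a`` as the leading neuron and train j of ``spikes_b`` as the
    following one.  Used to build surrogate null distributions."""
    if spikes_a.duration_ms != spikes_b.duration_ms:
        raise ValueError("spike sets must share a common duration")
    W = int(round(delay_window / bin_ms))
    L = 2 * W
    SA, n_bins = _binned_counts(spikes_a, bin_ms)
    SB, _ = _binned_counts(spikes_b, bin_ms)
    if L >= n_bins:
        raise ValueError("recording too short for the requested delay window")
    ccg = _ccg_stack(SA, SB, L, self_pair=False)
    signed = _signed_deviation(ccg, L, W)
    ca = np.asarray(SA.sum(axis=1)).ravel()
    cb = np.asarray(SB.sum(axis=1)).ravel()
    norm = np.sqrt(np.outer(ca, cb))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(norm > 0, signed / norm, 0.0)


def estimate_pair(
    times_i,
    times_j,
    duration_ms: float,
    delay_window: float = 25.0,
    bin_ms: float = 1.0,
) -> float:
    """Single-pair value of the default estimator (same statistic as
    :func:`estimate_cm` restricted to the ordered pair i -> j)."""
    times_i = np.asarray(times_i, dtype=float)
    times_j = np.asarray(times_j, dtype=float)
    if times_i.size == 0 or times_j.size == 0:
        return 0.0
    W = int(round(delay_window / bin_ms))
    L = 2 * W
    n_bins = max(int(np.ceil(duration_ms / bin_ms)), 1)
    if L >= n_bins:
        raise ValueError("recording too short for the requested delay window")
    xi = np.bincount(
        np.minimum((times_i / bin_ms).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    ).astype(np.float64)
    xj = np.bincount(
        np.minimum((times_j / bin_ms).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    ).astype(np.float64)
    ccg = np.empty((2 * L + 1, 1, 1))
    for lag in range(-L, L + 1):
        if lag > 0:
            ccg[L + lag, 0, 0] = xi[:-lag] @ xj[lag:]
        elif lag < 0:
            ccg[L + lag, 0, 0] = xi[-lag:] @ xj[:lag]
        else:
            ccg[L, 0, 0] = xi @ xj
    signed = _signed_deviation(ccg, L, W)[0, 0]
    return float(signed / np.sqrt(times_i.size * times_j.size))


def shuffle_train(spike_times, duration_ms: float, seed=None) -> np.ndarray:
    """Uniform spike-time shuffle: same spike count, i.i.d. uniform times on
    [0, duration], sorted.  Destroys all ISI structure while preserving the
    firing rate exactly."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and duration_ms < spike_times.max():
        raise ValueError("duration must cover the latest spike")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.sort(rng.uniform(0.0, duration_ms, size=spike_times.size))
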