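"""Thresholding methods mapping a full signed connectivity matrix (CM) onto a
pruned functional matrix (FM).

Four methods are provided:

* ``hard_threshold`` (HT): keeps positive entries above mu_exc + n_exc * sd_exc
  and negative entries below mu_inh - n_inh * sd_inh, with the statistics
  computed over the nonzero entries of each sign separately.
* ``ddt`` — the double-threshold algorithm.  Step 1 applies HT, splitting the
  CM into kept links (T1CM) and rejected ones (RM).  Step 2 builds, for each
  rejected element ij, a second threshold from the other same-sign nonzero
  entries of RM's row i (the element itself excluded):

      Th_exc(ij) = mu + m_exc * sd,    Th_inh(ij) = mu - m_inh * sd.

  The row acts as a pseudo-surrogate null distribution: when most row entries
  are spurious, a true link stands out against them even if it failed the
  global first threshold.  Step 3 recovers the RM elements exceeding their
  row threshold (T2CM); step 4 returns FM = T1CM union T2CM (disjoint by
  construction).
* ``density_threshold`` (DT): keeps exactly the M_e strongest excitatory and
  M_i most-negative inhibitory entries.
* ``shuffle_threshold`` (SH): compares each entry against the distribution of
  estimator values obtained from uniformly shuffled surrogate copies of the
  target train, keeping entries whose one-sided z-score is significant.

Standard deviations are sample SDs (n - 1 denominator) throughout, and both
DDT thresholds use strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm as _norm

from .fc_estimation import ConnectivityMatrix, cross_values, shuffle_train
from .simulator import SpikeTrainSet

__all__ = [
    "ThresholdResult",
    "hard_threshold",
    "ddt",
    "density_threshold",
    "shuffle_threshold",
]

#: fewest same-sign row entries needed to form a second-threshold statistic;
#: small networks (a handful of neurons) need this lowered to 2
MIN_ROW_CANDIDATES = 5


@dataclass
class ThresholdResult:
    """Pruned matrix plus (for DDT) the intermediate matrices."""

    fm: np.ndarray
    method_tag: str
    params: dict = field(default_factory=dict)
    t1cm: np.ndarray | None = None
    rm: np.ndarray | None = None
    tm: np.ndarray | None = None
    t2cm: np.ndarray | None = None

    @property
    def n_exc_links(self) -> int:
        return int(np.count_nonzero(self.fm > 0))

    @property
    def n_inh_links(self) -> int:
        return int(np.count_nonzero(self.fm < 0))

    @property
    def n_links(self) -> int:
        return self.n_exc_links + self.n_inh_links


def _as_values(cm) -> np.ndarray:
    if isinstance(cm, ConnectivityMatrix):
        return cm.values
    return np.asarray(cm, dtype=float)


def _sign_stats(values: np.ndarray, positive: bool):
    sel = values[values > 0] if positive else values[values < 0]
    if sel.size == 0:
        return None
    mu = sel.mean()
    sd = sel.std(ddof=1) if sel.size > 1 else 0.0
    return mu, sd


def hard_threshold(cm, n_exc: float = 1.0, n_inh: float = 2.0,
                   signs: str = "both") -> ThresholdResult:
    """Global mean +/- n * SD threshold, applied per sign (strict inequality).

    ``signs="excitatory"`` restricts thresholding to the positive side, for
    networks known to carry no inhibitory population (negative estimator
    values are then pure noise and are never selected).
    """
    if signs not in ("both", "excitatory"):
        raise ValueError("signs must be 'both' or 'excitatory'")
    values = _as_values(cm)
    fm = np.zeros_like(values)
    pos_stats = _sign_stats(values, True)
    if pos_stats is None:
        warnings.warn("no positive entries: excitatory output is empty")
    else:
        mu, sd = pos_stats
        keep = values > mu + n_exc * sd
        fm[keep] = values[keep]
    if signs == "both":
        neg_stats = _sign_stats(values, False)
        if neg_stats is None:
            warnings.warn("no negative entries: inhibitory output is empty")
        else:
            mu, sd = neg_stats
            keep = values < mu - n_inh * sd
            fm[keep] = values[keep]
    return ThresholdResult(
        fm=fm, method_tag="HT",
        params={"n_exc": n_exc, "n_inh": n_inh, "signs": signs},
    )


def _row_second_threshold(row, candidates, pool, m, positive, min_candidates,
                          global_sd=0.0):
    """Per-element second thresholds for one RM row.

    ``candidates`` marks the row elements of the considered sign;  ``pool``
    marks the entries contributing to the mean/SD statistics (same-sign
    entries in "split" mode, all nonzero entries in "pooled" mode).  Each
    element is compared against the statistics of the pool with itself
    excluded; elements whose exclusion leaves fewer than ``min_candidates``
    values get a NaN threshold (conservatively rejected).

    In the small-row regime (fewer than five pool values) a two- or
    three-sample SD is an unreliable noise estimate and can collapse to ~0;
    there the row SD is floored by ``global_sd``, the SD of the corresponding
    entries over the whole rejected matrix.  Rows with at least five values
    use the pure row statistics.
    """
    thr = np.full(row.shape, np.nan)
    vals = row[pool]
    cnt = vals.size
    if cnt - 1 < max(min_candidates, 2):
        return thr
    s1, s2 = vals.sum(), np.square(vals).sum()
    idx = np.flatnonzero(candidates)
    x = row[idx]
    n_excl = cnt - 1
    mu = (s1 - x) / n_excl
    var = (s2 - x * x - n_excl * mu * mu) / (n_excl - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    if n_excl < 5:
        sd = np.maximum(sd, global_sd)
    thr[idx] = mu + m * sd if positive else mu - m * sd
    return thr


def ddt(
    cm,
    n_exc: float = 1.0,
    n_inh: float = 2.0,
    m_exc: float = 3.0,
    m_inh: float = 3.0,
    min_row_candidates: int = MIN_ROW_CANDIDATES,
    row_stats: str = "split",
    signs: str = "both",
) -> ThresholdResult:
    """Double-threshold pruning (see module docstring).

    Returns the FM and all intermediates (T1CM, RM, TM, T2CM).  TM holds the
    per-element second thresholds (NaN where undefined).

    ``row_stats`` controls the pool behind the second-threshold statistics:
    "split" (default) uses only same-sign nonzero row entries, keeping the
    pseudo-surrogate argument sign-consistent on large mixed-sign matrices;
    "pooled" uses all nonzero row entries, appropriate for small matrices
    where a sign-split row would be too short to form a null distribution.
    """
    if row_stats not in ("split", "pooled"):
        raise ValueError("row_stats must be 'split' or 'pooled'")
    values = _as_values(cm)
    first = hard_threshold(values, n_exc=n_exc, n_inh=n_inh, signs=signs)
    t1cm = first.fm
    rm = np.where(t1cm == 0, values, 0.0)
    np.fill_diagonal(rm, 0.0)

    tm = np.full(values.shape, np.nan)
    t2cm = np.zeros_like(values)
    # robust global noise scale (MAD-based): the rejected matrix is mostly
    # null values, but the few rejected true links must not inflate the floor
    _gsd = {}
    for key, sel in (("pos", rm[rm > 0]), ("neg", rm[rm < 0]),
                     ("all", rm[rm != 0])):
        if sel.size > 1:
            _gsd[key] = 1.4826 * float(np.median(np.abs(sel - np.median(sel))))
        else:
            _gsd[key] = 0.0
    for i in range(values.shape[0]):
        row = rm[i]
        branches = ((True, m_exc), (False, m_inh))
        if signs == "excitatory":
            branches = ((True, m_exc),)
        for positive, m in branches:
            cand = row > 0 if positive else row < 0
            if not cand.any():
                continue
            pool = cand if row_stats == "split" else row != 0
            if row_stats == "split":
                global_sd = _gsd["pos"] if positive else _gsd["neg"]
            else:
                global_sd = _gsd["all"]
            thr = _row_second_threshold(row, cand, pool, m, positive,
                                        min_row_candidates,
                                        global_sd=global_sd)
            tm[i, cand] = thr[cand]
            ok = np.zeros_like(cand)
            defined = cand & np.isfinite(thr)
            if positive:
                ok[defined] = row[defined] > thr[defined]
            else:
                ok[defined] = row[defined] < thr[defined]
            t2cm[i, ok] = row[ok]

    fm = t1cm + t2cm  # disjoint supports by construction
    return ThresholdResult(
        fm=fm,
        method_tag="DDT",
        params={
            "n_exc": n_exc, "n_inh": n_inh, "m_exc": m_exc, "m_inh": m_inh,
            "min_row_candidates": min_row_candidates, "row_stats": row_stats,
            "signs": signs,
        },
        t1cm=t1cm,
        rm=rm,
        tm=tm,
        t2cm=t2cm,
    )


def density_threshold(cm, m_exc_links: int, m_inh_links: int) -> ThresholdResult:
    """Keep exactly the requested number of strongest links per sign.

    Ties at the cut are broken by keeping the earliest entries in row-major
    order.  Requests exceeding the available entries are clipped with a
    warning.
    """
    values = _as_values(cm)
    fm = np.zeros_like(values)
    flat = values.ravel()
    for positive, m in ((True, m_exc_links), (False, m_inh_links)):
        if m < 0:
            raise ValueError("link counts must be non-negative")
        avail = int((flat > 0).sum()) if positive else int((flat < 0).sum())
        if m > avail:
            warnings.warn(
                f"requested {m} {'excitatory' if positive else 'inhibitory'} "
                f"links but only {avail} available: clipped"
            )
            m = avail
        if m == 0:
            continue
        key = -flat if positive else flat
        # stable sort on the key keeps row-major order among exact ties
        order = np.argsort(key, kind="stable")
        chosen = order[:m]
        fm.ravel()[chosen] = flat[chosen]
    return ThresholdResult(
        fm=fm, method_tag="DT",
        params={"m_exc_links": m_exc_links, "m_inh_links": m_inh_links},
    )


def shuffle_threshold(
    spikes: SpikeTrainSet,
    cm: ConnectivityMatrix,
    n_shuffles: int = 100,
    alpha_exc: float = 0.01,
    alpha_inh: float = 0.01,
    seed: int = 0,
) -> ThresholdResult:
    """Surrogate-based thresholding.

    For every ordered pair (i, j) a null distribution of estimator values is
    built by re-estimating the connection between train i and ``n_shuffles``
    uniformly shuffled copies of train j.  Entries are kept when the one-sided
    z-score of the observed value against the null exceeds the critical value
    at the requested significance (upper tail for positive entries, lower for
    negative ones).
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20 for a stable z-test")
    for alpha in (alpha_exc, alpha_inh):
        if not 0.0 < alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
    if not isinstance(cm, ConnectivityMatrix):
        raise TypeError("shuffle_threshold needs the estimator's ConnectivityMatrix")
    rng = np.random.default_rng(seed)
    n = spikes.n_neurons
    mean = np.zeros((n, n))
    m2 = np.zeros((n, n))
    for s in range(n_shuffles):
        ids, times = [], []
        for j in range(n):
            tj = shuffle_train(spikes.spikes_of(j), spikes.duration_ms, rng)
            ids.append(np.full(tj.size, j))
            times.append(tj)
        surrogate = SpikeTrainSet(
            np.concatenate(ids), np.concatenate(times), n, spikes.duration_ms
        )
        vals = cross_values(
            spikes, surrogate, delay_window=cm.delay_window, bin_ms=cm.bin_ms
        )
        delta = vals - mean
        mean += delta / (s + 1)
        m2 += delta * (vals - mean)
    sd = np.sqrt(m2 / (n_shuffles - 1))
    values = cm.values
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    fm = np.zeros_like(values)
    keep_pos = (values > 0) & (z > _norm.ppf(1.0 - alpha_exc))
    keep_neg = (values < 0) & (z < _norm.ppf(alpha_inh))
    fm[keep_pos] = values[keep_pos]
    fm[keep_neg] = values[keep_neg]
    np.fill_diagonal(fm, 0.0)
    return ThresholdResult(
        fm=fm, method_tag="SH",
        params={"n_shuffles": n_shuffles, "alpha_exc": alpha_exc,
                "alpha_inh": alpha_inh, "seed": seed},
    )
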