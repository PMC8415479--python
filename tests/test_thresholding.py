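"""Thresholding methods: hand-computed examples, the step-by-step oracle,
set-theoretic invariants, and the surrogate method's calibration."""

import statistics

import numpy as np
import pytest

from fcthresh.fc_estimation import ConnectivityMatrix, estimate_cm
from fcthresh.thresholding import (
    ddt,
    density_threshold,
    hard_threshold,
    shuffle_threshold,
    _row_second_threshold,
)

from conftest import poisson_trains


def random_cm(n, seed, inh_fraction=0.3, scale=1.0):
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, scale, size=(n, n))
    flip = rng.random((n, n)) < inh_fraction
    v = np.where(flip, -np.abs(v), np.abs(v))
    np.fill_diagonal(v, 0.0)
    return v


class TestHardThreshold:
    def test_hand_example(self):
        """Positive entries {10,1,1,1,1}: mu=2.8, sd=4.025 -> keeps only 10."""
        v = np.zeros((3, 3))
        v[0, 1], v[0, 2], v[1, 0], v[1, 2], v[2, 0] = 10, 1, 1, 1, 1
        res = hard_threshold(v, n_exc=1.0)
        kept = v[res.fm != 0]
        assert kept.tolist() == [10.0]

    def test_degenerate_identical_positives_keep_nothing(self):
        v = np.ones((4, 4))
        np.fill_diagonal(v, 0.0)
        res = hard_threshold(v)
        assert res.n_links == 0

    def test_sign_separation(self):
        v = random_cm(30, 0)
        res = hard_threshold(v, 1.0, 1.0)
        assert np.all(res.fm[v > 0] >= 0)
        pos = v[v > 0]
        thr = pos.mean() + pos.std(ddof=1)
        assert set(map(tuple, np.argwhere(res.fm > 0))) == set(
            map(tuple, np.argwhere(v > thr))
        )


class TestSecondThresholdRow:
    def test_hand_example_row(self):
        """RM row [4,1,1,1,0], m=1: value 4 recovered, values 1 rejected."""
        row = np.array([4.0, 1.0, 1.0, 1.0, 0.0])
        cand = row > 0
        thr = _row_second_threshold(row, cand, cand, 1.0, True, 2)
        assert thr[0] == pytest.approx(1.0)  # mu=1, sd=0 over {1,1,1}
        assert thr[1] == pytest.approx(2.0 + np.sqrt(3.0))
        assert row[0] > thr[0]
        assert row[1] < thr[1]

    def test_too_few_candidates_rejected(self):
        row = np.array([4.0, 1.0, 0.0, 0.0])
        cand = row > 0
        thr = _row_second_threshold(row, cand, cand, 1.0, True, 2)
        assert np.all(np.isnan(thr))


def oracle_ddt(values, n_exc, n_inh, m_exc, m_inh, min_row, row_stats):
    """Literal step-by-step transcription of the double-threshold procedure
    using plain Python loops and the statistics module (independent of the
    vectorized implementation)."""
    n = len(values)
    pos = [values[i][j] for i in range(n) for j in range(n)
           if values[i][j] > 0]
    neg = [values[i][j] for i in range(n) for j in range(n)
           if values[i][j] < 0]
    t1 = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            x = values[i][j]
            if x > 0 and len(pos) > 1:
                if x > statistics.mean(pos) + n_exc * statistics.stdev(pos):
                    t1[i][j] = x
            if x < 0 and len(neg) > 1:
                if x < statistics.mean(neg) - n_inh * statistics.stdev(neg):
                    t1[i][j] = x
    rm = [[values[i][j] if (t1[i][j] == 0 and i != j) else 0.0
           for j in range(n)] for i in range(n)]
    rm_flat = [rm[i][j] for i in range(n) for j in range(n) if rm[i][j] != 0]
    rm_pos = [x for x in rm_flat if x > 0]
    rm_neg = [x for x in rm_flat if x < 0]

    def mad_scale(xs):
        if len(xs) < 2:
            return 0.0
        med = statistics.median(xs)
        return 1.4826 * statistics.median([abs(x - med) for x in xs])

    t2 = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            x = rm[i][j]
            if x == 0:
                continue
            positive = x > 0
            m = m_exc if positive else m_inh
            if row_stats == "split":
                pool = [rm[i][k] for k in range(n)
                        if rm[i][k] != 0 and (rm[i][k] > 0) == positive]
                gsd = mad_scale(rm_pos if positive else rm_neg)
            else:
                pool = [rm[i][k] for k in range(n) if rm[i][k] != 0]
                gsd = mad_scale(rm_flat)
            pool_excl = list(pool)
            pool_excl.remove(x)
            if len(pool_excl) < max(min_row, 2):
                continue
            mu = statistics.mean(pool_excl)
            sd = statistics.stdev(pool_excl)
            if len(pool_excl) < 5:
                sd = max(sd, gsd)
            if positive and x > mu + m * sd:
                t2[i][j] = x
            if not positive and x < mu - m * sd:
                t2[i][j] = x
    fm = [[t1[i][j] + t2[i][j] for j in range(n)] for i in range(n)]
    return np.array(t1), np.array(rm), np.array(t2), np.array(fm)


class TestDDT:
    @pytest.mark.parametrize("n", [5, 8])
    @pytest.mark.parametrize("row_stats", ["split", "pooled"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_step_by_step_oracle(self, n, row_stats, seed):
        v = random_cm(n, seed)
        res = ddt(v, 1.0, 1.0, 1.0, 1.0, min_row_candidates=2,
                  row_stats=row_stats)
        t1, rm, t2, fm = oracle_ddt(v, 1.0, 1.0, 1.0, 1.0, 2, row_stats)
        np.testing.assert_allclose(res.t1cm, t1, atol=1e-12)
        np.testing.assert_allclose(res.rm, rm, atol=1e-12)
        np.testing.assert_allclose(res.t2cm, t2, atol=1e-12)
        np.testing.assert_allclose(res.fm, fm, atol=1e-12)

    def test_intermediate_set_identities(self):
        v = random_cm(40, 7)
        res = ddt(v)
        sup = lambda m: set(map(tuple, np.argwhere(m != 0)))
        assert sup(res.t1cm) & sup(res.t2cm) == set()
        assert sup(res.fm) == sup(res.t1cm) | sup(res.t2cm)
        assert sup(res.rm) == sup(v) - sup(res.t1cm)
        assert sup(res.fm) <= sup(v)
        # signs preserved
        assert np.all(np.sign(res.fm[res.fm != 0])
                      == np.sign(v[res.fm != 0]))

    def test_all_zero_cm(self):
        res = ddt(np.zeros((6, 6)))
        assert res.n_links == 0
        assert np.count_nonzero(res.t1cm) == 0
        assert np.count_nonzero(res.t2cm) == 0

    def test_superset_of_hard_threshold(self):
        for seed in range(5):
            v = random_cm(30, seed)
            ht = hard_threshold(v)
            for m in (0.5, 1.0, 3.0):
                res = ddt(v, m_exc=m, m_inh=m)
                assert set(map(tuple, np.argwhere(ht.fm != 0))) <= set(
                    map(tuple, np.argwhere(res.fm != 0))
                )

    def test_degenerates_to_hard_threshold_in_large_m_limit(self):
        v = random_cm(30, 3)
        res = ddt(v, m_exc=1e12, m_inh=1e12)
        ht = hard_threshold(v)
        np.testing.assert_array_equal(res.fm, ht.fm)
        assert np.count_nonzero(res.t2cm) == 0

    def test_monotonicity(self):
        """Raising n shrinks T1CM; raising m shrinks T2CM."""
        v = random_cm(40, 9)
        t1_sizes = [np.count_nonzero(ddt(v, n_exc=n).t1cm)
                    for n in (0.5, 1.0, 2.0)]
        assert t1_sizes == sorted(t1_sizes, reverse=True)
        t2_sizes = [np.count_nonzero(ddt(v, m_exc=m).t2cm)
                    for m in (1.0, 2.0, 4.0)]
        assert t2_sizes == sorted(t2_sizes, reverse=True)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        v = random_cm(25, 11)
        perm = rng.permutation(25)
        for method in (
            lambda x: ddt(x).fm,
            lambda x: hard_threshold(x).fm,
            lambda x: density_threshold(x, 30, 10).fm,
        ):
            direct = method(v[np.ix_(perm, perm)])
            permuted = method(v)[np.ix_(perm, perm)]
            np.testing.assert_allclose(direct, permuted)


class TestDensityThreshold:
    def test_keeps_exactly_m_strongest(self):
        v = np.zeros((3, 3))
        v[0, 1], v[0, 2], v[1, 0], v[1, 2], v[2, 0] = 5, 4, 3, 2, 1
        res = density_threshold(v, 2, 0)
        assert sorted(v[res.fm != 0].tolist()) == [4.0, 5.0]

    def test_full_budget_returns_support(self):
        v = random_cm(20, 2)
        n_pos = int((v > 0).sum())
        n_neg = int((v < 0).sum())
        res = density_threshold(v, n_pos, n_neg)
        assert res.n_links == n_pos + n_neg

    def test_overflow_clipped_with_warning(self):
        v = random_cm(10, 3)
        with pytest.warns(UserWarning):
            res = density_threshold(v, 10_000, 0)
        assert res.n_exc_links == int((v > 0).sum())

    def test_tie_break_row_major(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = v[2, 0] = 2.0  # exact ties
        res = density_threshold(v, 2, 0)
        assert set(map(tuple, np.argwhere(res.fm != 0))) == {(0, 1), (1, 0)}

    def test_ddt_calibration_equalizes_link_counts(self):
        v = random_cm(40, 5)
        d = ddt(v)
        dt = density_threshold(v, d.n_exc_links, d.n_inh_links)
        assert dt.n_exc_links == d.n_exc_links
        assert dt.n_inh_links == d.n_inh_links


class TestShuffleThreshold:
    def test_false_positive_rate_on_poisson_pairs(self):
        """~200 independent Poisson pairs at alpha = 0.01: the number of
        retained edges lies in the exact binomial 99% interval."""
        from scipy.stats import binom

        sp = poisson_trains(15, 10.0, 200_000.0, seed=8)
        cm = estimate_cm(sp)
        res = shuffle_threshold(sp, cm, n_shuffles=40, seed=9)
        n_pairs = 15 * 14
        lo, hi = binom.ppf([0.005, 0.995], n_pairs, 0.01)
        assert lo <= res.n_links <= hi

    def test_parameter_validation(self):
        sp = poisson_trains(4, 5.0, 5_000.0, seed=1)
        cm = estimate_cm(sp)
        with pytest.raises(ValueError):
            shuffle_threshold(sp, cm, n_shuffles=5)
        with pytest.raises(ValueError):
            shuffle_threshold(sp, cm, alpha_exc=0.7)

    def test_detects_planted_connection(self):
        """A train echoed at +5 ms is kept by the surrogate test."""
        from fcthresh.simulator import SpikeTrainSet

        rng = np.random.default_rng(3)
        T = 100_000.0
        trains = [np.sort(rng.uniform(0, T, 800)) for _ in range(3)]
        trains.append(np.clip(trains[0] + 5.0, 0, T))  # neuron 3 echoes 0
        full = SpikeTrainSet(
            np.concatenate([np.full(len(t), i) for i, t in enumerate(trains)]),
            np.concatenate(trains), 4, T,
        )
        cm = estimate_cm(full)
        res = shuffle_threshold(full, cm, n_shuffles=30, seed=6)
        assert res.fm[0, 3] > 0
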