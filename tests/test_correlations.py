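import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsync import correlations as C
from popsync._binning import bin_windows
from popsync.synthetic import simulate_correlated_population
from conftest import make_session, make_train


class TestPopulationRate:
    def test_counts_sum_across_units(self):
        trains = [make_train(f"u{i}", [0.0055], 0.01) for i in range(3)]
        sess = make_session(trains)
        counts = C.population_rate(sess, bin_ms=1, epoch=[(0.0, 0.01)])
        expected = np.zeros(10, dtype=int)
        expected[5] = 3
        np.testing.assert_array_equal(counts, expected)

    def test_single_unit_equals_own_binned_train(self):
        tr = make_train("u", [0.001, 0.0042, 0.0071], 0.01)
        sess = make_session([tr])
        counts = C.population_rate(sess, bin_ms=1, epoch=[(0.0, 0.01)])
        own, _ = bin_windows(tr.spike_times, [(0.0, 0.01)], 1e-3)
        np.testing.assert_array_equal(counts, own)

    def test_empty_epoch_rejected(self):
        sess = make_session([make_train("u", [0.5], 1.0)])
        with pytest.raises(ValueError, match="epoch"):
            C.population_rate(sess, epoch=[])


class TestPopulationCoupling:
    def test_perfectly_coincident_unit_matches_brute_force(self):
        # unit 0 fires with one spike from each of 9 others in its bin:
        # stPR(0) = 9 spikes / 1 ms bin = 9000 Hz before normalization
        times = 0.1 + 0.1 * np.arange(50) + 0.0005
        trains = [make_train(f"u{i}", times + i * 1e-5, 10.0)
                  for i in range(10)]
        sess = make_session(trains)
        res = C.population_coupling(sess, epoch=[(0.0, 10.0)],
                                    n_shuffles=200, seed=3)
        r0 = res[0]
        assert r0.stpr_lag0_hz == pytest.approx(9000.0)
        # null is sparse (450 spikes over 10000 bins): its median is small
        # next to the observed value
        assert 0.0 <= r0.shuffle_median_hz < 200.0
        assert r0.coupling_hz == pytest.approx(
            r0.stpr_lag0_hz - r0.shuffle_median_hz)
        assert r0.coupling_hz == pytest.approx(9000.0, rel=0.03)

    def test_invariant_to_unit_relabeling(self):
        sess, _ = simulate_correlated_population(8, 30.0, 10.0, 0.3, 5.0,
                                                 seed=5)
        res = C.population_coupling(sess, epoch=[(0.0, 30.0)], seed=7)
        sess_rev = sess.subset(sess.unit_ids[::-1])
        res_rev = C.population_coupling(sess_rev, epoch=[(0.0, 30.0)], seed=7)
        a = {r.unit_id: r.stpr_lag0_hz for r in res}
        b = {r.unit_id: r.stpr_lag0_hz for r in res_rev}
        assert a == b

    def test_shuffled_trigger_has_zero_median_coupling(self):
        # redraw every unit's spikes uniformly: coupling centered on 0
        rng = np.random.default_rng(11)
        trains = []
        for i in range(20):
            t = np.sort(rng.uniform(0, 100.0, 1000))
            t = t[np.concatenate([[True], np.diff(t) > 1e-4])]
            trains.append(make_train(f"u{i}", t, 100.0))
        sess = make_session(trains)
        res = C.population_coupling(sess, epoch=[(0.0, 100.0)], seed=13)
        vals = C.coupling_values(res)
        from scipy.stats import binomtest

        n_pos = int(np.sum(vals > 0))
        assert binomtest(n_pos, vals.size).pvalue > 0.01

    def test_sparse_unit_flagged_null(self):
        trains = [make_train("sparse", [1.0, 2.0], 50.0)]
        rng = np.random.default_rng(2)
        for i in range(5):
            t = np.sort(rng.uniform(0, 50, 400))
            t = t[np.concatenate([[True], np.diff(t) > 1e-4])]
            trains.append(make_train(f"u{i}", t, 50.0))
        sess = make_session(trains)
        res = C.population_coupling(sess, epoch=[(0.0, 50.0)], seed=1)
        sparse = [r for r in res if r.unit_id == "sparse"][0]
        assert sparse.coupling_hz is None and "spikes" in sparse.reason

    def test_too_few_units_rejected(self):
        sess = make_session([make_train(f"u{i}", [1.0 + i / 100], 10.0)
                             for i in range(3)])
        with pytest.raises(ValueError, match=">= 5"):
            C.population_coupling(sess, epoch=[(0.0, 10.0)], seed=1)

    def test_seed_required(self):
        sess, _ = simulate_correlated_population(5, 5.0, 10.0, 0.0, 0.0,
                                                 seed=1)
        with pytest.raises(ValueError, match="seed"):
            C.population_coupling(sess, epoch=[(0.0, 5.0)], seed=None)

    def test_monotone_in_injected_participation(self):
        means = []
        for p in (0.0, 0.2, 0.5):
            sess, _ = simulate_correlated_population(
                12, 60.0, 10.0, p, 8.0, sigma_sync_ms=0.5, seed=23)
            res = C.population_coupling(sess, epoch=[(0.0, 60.0)], seed=29)
            means.append(C.coupling_values(res).mean())
        assert means[0] < means[1] < means[2]


class TestPairwiseSynchrony:
    def test_worked_ten_bin_instance(self):
        # counts A=[0,1,0,1,0,1,0,0,0,0], B=[0,1,0,1,0,0,0,1,0,0]
        a = make_train("a", [0.0015, 0.0035, 0.0055], 0.012)
        b = make_train("b", [0.00151, 0.00351, 0.0075], 0.012)
        sess = make_session([a, b])
        # relax the 10-spike floor via direct Pearson on the binned counts
        ca, _ = bin_windows(a.spike_times, [(0.0, 0.010)], 1e-3)
        cb, _ = bin_windows(b.spike_times, [(0.0, 0.010)], 1e-3)
        r = C._pearson(ca.astype(float), cb.astype(float))
        assert r == pytest.approx(0.5238095238095238, abs=1e-12)

    def test_identical_trains_fully_synchronous(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 20, 300))
        t = t[np.concatenate([[True], np.diff(t) > 1e-3])]
        sess = make_session([make_train("a", t, 20.0),
                             make_train("b", t, 20.0)])
        (pair,) = C.pairwise_synchrony(sess, epoch=[(0.0, 20.0)],
                                       with_ccg=False)
        assert pair.sync_r == pytest.approx(1.0)

    def test_one_bin_shift_moves_ccg_peak(self):
        t = np.sort(np.random.default_rng(2).uniform(1, 19, 400))
        t = t[np.concatenate([[True], np.diff(t) > 2e-3])]
        sess = make_session([make_train("a", t, 20.0),
                             make_train("b", t + 1e-3, 20.0)])
        (pair,) = C.pairwise_synchrony(sess, epoch=[(0.0, 20.0)])
        peak = pair.lags_ms[np.nanargmax(pair.ccg)]
        assert abs(peak) == 1.0
        lag0 = pair.ccg[pair.lags_ms == 0][0]
        assert abs(lag0) < 0.2

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_ccg_antisymmetric_under_pair_swap(self, seed):
        rng = np.random.default_rng(seed)
        n_bins = rng.integers(10, 50)
        dur = n_bins * 1e-3
        trains = []
        for name in "ab":
            t = np.sort(rng.uniform(0, dur, rng.integers(5, 30)))
            t = t[np.concatenate([[True], np.diff(t) > 6e-5])]
            trains.append(make_train(name, t, dur + 0.001))
        ca, sl = bin_windows(trains[0].spike_times, [(0.0, dur)], 1e-3)
        cb, _ = bin_windows(trains[1].spike_times, [(0.0, dur)], 1e-3)
        _, fwd = C.cross_correlogram(ca.astype(float), cb.astype(float),
                                     sl, 5)
        _, rev = C.cross_correlogram(cb.astype(float), ca.astype(float),
                                     sl, 5)
        np.testing.assert_array_equal(fwd, rev[::-1])


class TestNoiseAndSignal:
    def test_unit_with_itself_is_unity(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 100, 500))
        t = t[np.concatenate([[True], np.diff(t) > 1e-3])]
        sess = make_session([make_train("a", t, 100.0),
                             make_train("b", t + 1e-5, 100.0)])
        wins = [(k * 2.0, k * 2.0 + 1.5) for k in range(50)]
        (pair,) = C.noise_correlations(sess, wins)
        assert pair.noise_r == pytest.approx(1.0)

    def test_independent_pairs_bounded_by_fisher(self):
        sess, _ = simulate_correlated_population(2, 150.0, 10.0, 0.0, 0.0,
                                                 seed=31)
        wins = [(k * 1.5, k * 1.5 + 1.5) for k in range(100)]
        (pair,) = C.noise_correlations(sess, wins)
        assert abs(pair.noise_r) < 0.3

    def test_too_few_windows_rejected(self):
        sess, _ = simulate_correlated_population(2, 10.0, 10.0, 0.0, 0.0,
                                                 seed=1)
        with pytest.raises(ValueError, match="windows"):
            C.noise_correlations(sess, [(0.0, 1.5)])

    def test_affine_mean_psths_correlate_exactly(self):
        y = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        assert C.signal_correlation_from_psths(y, 2.5 * y + 1.0) == \
            pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_four_bins_rejected(self):
        with pytest.raises(ValueError, match="4"):
            C.signal_correlation_from_psths(np.ones(3), np.ones(3))


class TestStratify:
    def test_all_superficial_leaves_deep_empty(self):
        sess = make_session([make_train(f"u{i}", [1.0 + i / 100], 10.0)
                             for i in range(4)], depths=[100.0] * 4)
        strata = C.stratify(sess)
        assert strata["deep"] == []
        assert len(strata["superficial"]) == 4

    def test_boundary_is_half_open(self):
        sess = make_session([make_train("a", [1.0], 10.0),
                             make_train("b", [1.01], 10.0)],
                            depths=[239.9, 240.0])
        strata = C.stratify(sess)
        assert strata["superficial"] == ["a"]
        assert strata["deep"] == ["b"]

    def test_small_stratum_rejected_for_coupling(self):
        sess, _ = simulate_correlated_population(6, 10.0, 10.0, 0.0, 0.0,
                                                 seed=1)
        # force all units superficial
        for _, m in sess.units:
            m.depth_um = 100.0
        with pytest.raises(ValueError, match="deep"):
            C.population_coupling(sess, epoch=[(0.0, 10.0)], stratum="deep",
                                  seed=1)
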