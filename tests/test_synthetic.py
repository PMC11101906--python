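import numpy as np
import pytest

from popsync.signals import lfp_spectrum, waveform_features
from popsync.synthetic import (
    PopulationSpec,
    ProtocolSpec,
    WaveformClass,
    orthogonal_tuning_pairs,
    preset_condition,
    simulate_correlated_population,
    simulate_lfp,
    simulate_session,
    simulate_waveforms,
)


def _quiet_pop(**kw):
    """Population with no evoked response and no shared structure."""
    base = dict(baseline_hz=10.0, threshold_mN=np.inf, p_event=0.0,
                event_rate_on_hz=0.0, event_rate_sustained_hz=0.0,
                event_rate_off_hz=0.0, gain_cv=0.0)
    base.update(kw)
    return PopulationSpec(**base)


class TestSimulateSession:
    def test_identical_seed_gives_identical_spikes(self):
        proto = ProtocolSpec(trials_per_force=2, brush_dur_s=0.0)
        pop = PopulationSpec(n_units=4)
        s1, _ = simulate_session(proto, pop, seed=5)
        s2, _ = simulate_session(proto, pop, seed=5)
        for (a, _), (b, _) in zip(s1.units, s2.units):
            np.testing.assert_array_equal(a.spike_times, b.spike_times)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_session(ProtocolSpec(), PopulationSpec(), seed=None)

    def test_poisson_count_matches_rate(self):
        # 10 Hz baseline, no stimulus response: count ~ Poisson(rate * T)
        proto = ProtocolSpec(forces_mN=(10.0,), trials_per_force=40,
                             brush_dur_s=0.0)
        pop = _quiet_pop(n_units=1)
        sess, _ = simulate_session(proto, pop, seed=11)
        tr = sess.units[0][0]
        expected = 10.0 * tr.t_stop
        assert abs(tr.n_spikes - expected) < 3 * np.sqrt(expected)

    def test_independent_units_have_near_zero_correlations(self):
        # p=0, gain_cv=0: pairwise count correlations vanish by construction
        sess, _ = simulate_correlated_population(
            12, 80.0, 10.0, 0.0, 0.0, seed=2)
        from popsync.correlations import noise_correlations

        wins = [(k, k + 1.0) for k in range(80)]
        rs = np.array([p.noise_r for p in noise_correlations(sess, wins)])
        assert abs(rs.mean()) < 2 * rs.std(ddof=1) / np.sqrt(rs.size)

    def test_event_participation_scales_co_spiking(self):
        # analytic oracle: expected lag-0 co-spike count for pair (i, j)
        # ~= N_events * p_i * p_j * q, with q the probability both jittered
        # spikes land in the same 1 ms bin (brute-force integral)
        p, sig_ms, dur = 0.6, 0.3, 120.0
        sess, _ = simulate_correlated_population(
            2, dur, 1.0, p, 10.0, sigma_sync_ms=sig_ms, seed=9)
        from popsync._binning import bin_session

        counts, _ = bin_session(sess, [(0.0, dur)], 1e-3)
        co = float(counts[0] @ counts[1])
        # brute force q by Monte Carlo on the jitter model
        rng = np.random.default_rng(0)
        a = rng.normal(0, sig_ms / 1e3, 200_000)
        b = rng.normal(0, sig_ms / 1e3, 200_000)
        u = rng.random(200_000) * 1e-3
        q = np.mean(np.floor((u + a) / 1e-3) == np.floor((u + b) / 1e-3))
        expected = 10.0 * dur * p * p * q
        assert abs(co - expected) < 4 * np.sqrt(expected)


class TestPresets:
    def test_sni_halves_superficial_participation(self):
        sham, gt_s = preset_condition("sham_like", 4)
        sni, gt_n = preset_condition("sni_like", 4)
        sup = np.asarray(gt_s.depth_um) < 240
        r = (np.asarray(gt_n.p_event)[sup].mean()
             / np.asarray(gt_s.p_event)[sup].mean())
        assert r == pytest.approx(0.5)
        deep_r = (np.asarray(gt_n.p_event)[~sup].mean()
                  / np.asarray(gt_s.p_event)[~sup].mean())
        assert deep_r == pytest.approx(1.0)

    def test_psi_ko_lowers_thresholds_one_force_step(self):
        forces = list(ProtocolSpec().forces_mN)
        _, gt_s = preset_condition("sham_like", 4)
        _, gt_k = preset_condition("psi_ko_like", 4)
        for ts, tk in zip(gt_s.threshold_mN, gt_k.threshold_mN):
            assert forces.index(tk) == max(forces.index(ts) - 1, 0)

    def test_pv_silenced_raises_rates_30pct(self):
        # expectation over seeds: baseline ratio 1.3 by construction
        ratios = []
        for seed in range(20):
            _, gs = preset_condition("sham_like", seed)
            _, gp = preset_condition("pv_silenced_like", seed)
            ratios.append(np.mean(gp.baseline_hz) / np.mean(gs.baseline_hz))
        assert np.mean(ratios) == pytest.approx(1.3)

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="sham_like"):
            preset_condition("nope", 1)


class TestWaveforms:
    def test_noiseless_durations_exact(self):
        classes = [WaveformClass(trough_to_peak_ms=0.3),
                   WaveformClass(trough_to_peak_ms=0.8)]
        wfs, labels, fs = simulate_waveforms(3, classes, 0.0, seed=1)
        for w, lab in zip(wfs, labels):
            f = waveform_features(w, fs)
            assert f.trough_to_peak_ms == pytest.approx(
                classes[lab].trough_to_peak_ms, abs=0.051)

    def test_noisy_class_means_recover_duration(self):
        classes = [WaveformClass(trough_to_peak_ms=0.3),
                   WaveformClass(trough_to_peak_ms=0.8)]
        wfs, labels, fs = simulate_waveforms(50, classes, 5.0, seed=2)
        durs = np.array([waveform_features(w, fs).trough_to_peak_ms
                         for w in wfs])
        for lab, cls in enumerate(classes):
            assert abs(durs[labels == lab].mean()
                       - cls.trough_to_peak_ms) < 0.05

    def test_single_class_emits_uniform_labels(self):
        _, labels, _ = simulate_waveforms(5, [WaveformClass()], 0.0, seed=1)
        assert set(labels) == {0}

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_waveforms(2, [WaveformClass()], -1.0, seed=1)


class TestLFP:
    def test_same_seed_identical_trace(self):
        a = simulate_lfp(12.0, 1000.0, 1.0, seed=4)
        b = simulate_lfp(12.0, 1000.0, 1.0, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_pure_one_over_f_matches_band_integral(self):
        # relative power over [30, 80] of a 1/f spectrum against (1, 250]:
        # ln(80/30) / ln(250/1)
        x = simulate_lfp(60.0, 1000.0, 1.0, seed=6)
        rel = lfp_spectrum(x, 1000.0).relative_band_power
        analytic = np.log(80 / 30) / np.log(250 / 1)
        assert rel == pytest.approx(analytic, rel=0.10)

    def test_pure_gamma_sinusoid_dominates_band(self):
        x = simulate_lfp(12.0, 1000.0, 0.0, gamma_hz=50.0, gamma_amp=1.0,
                         seed=7)
        assert lfp_spectrum(x, 1000.0).relative_band_power >= 0.95

    def test_gamma_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="gamma_hz"):
            simulate_lfp(12.0, 1000.0, 1.0, gamma_hz=600.0, gamma_amp=1.0,
                         seed=1)


class TestOrthogonalTuning:
    def test_pairs_orthogonal_after_centering_and_positive(self):
        W = orthogonal_tuning_pairs(20, 6, seed=3)
        assert np.all(W > 0)
        for k in range(20):
            a, b = W[2 * k] - W[2 * k].mean(), W[2 * k + 1] - W[2 * k + 1].mean()
            assert abs(a @ b) < 1e-9
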