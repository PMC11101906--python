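import numpy as np
import pytest

from popsync.io_model import StimulusEvent
from popsync.synthetic import PopulationSpec, ProtocolSpec, simulate_session
from popsync import tuning
from conftest import make_train


def _events(n, force=10.0, period=2.5, step=0.5, baseline=1.5):
    return [StimulusEvent("indentation", baseline + period * k,
                          baseline + period * k + step, k, force_mN=force)
            for k in range(n)]


class TestPSTH:
    def test_single_spike_per_trial_counts_to_100hz(self):
        evs = _events(10)
        times = np.sort([e.onset_s + 0.005 for e in evs])
        tr = make_train("u", times, 30.0)
        psth = tuning.compute_psth(tr, evs, bin_ms=10)
        post = psth.rate_hz[psth.bin_edges_s[:-1] >= -1e-9]
        assert post[0] == pytest.approx(100.0)
        assert np.all(post[1:] == 0)
        assert psth.baseline_hz == 0

    def test_stationary_poisson_baseline_subtracted_near_zero(self):
        rng = np.random.default_rng(8)
        evs = _events(200)
        t_stop = evs[-1].offset_s + 1.0
        times = np.sort(rng.uniform(0, t_stop, int(10 * t_stop)))
        times = times[np.concatenate([[True], np.diff(times) > 1e-4])]
        tr = make_train("u", times, t_stop)
        psth = tuning.compute_psth(tr, evs, variant="baseline_subtracted")
        se = np.sqrt(10.0 / (0.01 * 200)) / np.sqrt(psth.rate_hz.size)
        assert abs(psth.rate_hz.mean()) < 2 * se

    def test_zero_baseline_sd_zscore_flagged_nan(self):
        evs = _events(3)
        tr = make_train("u", [e.onset_s + 0.01 for e in evs], 10.0)
        psth = tuning.compute_psth(tr, evs, variant="zscored")
        assert np.all(np.isnan(psth.rate_hz))

    def test_no_trials_rejected(self):
        tr = make_train("u", [1.0], 10.0)
        with pytest.raises(ValueError, match="trial"):
            tuning.compute_psth(tr, [])


class TestWindowRates:
    def test_spike_in_sustained_window_only(self):
        evs = _events(1)
        tr = make_train("u", [evs[0].onset_s + 0.4], 10.0)
        per = tuning.window_rates(tr, evs)
        assert per["sustained_hz"] == pytest.approx(5.0)  # 1 spike / 0.2 s
        assert per["on_hz"] == 0 and per["off_hz"] == 0

    def test_spike_after_offset_is_off_response(self):
        evs = _events(1)
        tr = make_train("u", [evs[0].offset_s + 0.02], 10.0)
        per = tuning.window_rates(tr, evs)
        assert per["off_hz"] > 0
        assert per["on_hz"] == 0 and per["sustained_hz"] == 0

    def test_short_steps_rejected(self):
        evs = [StimulusEvent("indentation", 1.5, 1.6, 0, force_mN=10.0)]
        tr = make_train("u", [1.55], 10.0)
        with pytest.raises(ValueError, match="0.25"):
            tuning.window_rates(tr, evs)


class TestDetectThreshold:
    def test_deterministic_responder_only_at_75(self):
        evs = []
        k = 0
        for force in (1.0, 10.0, 75.0):
            for _ in range(10):
                evs.append(StimulusEvent("indentation", 1.5 + 2.5 * k,
                                         2.0 + 2.5 * k, k, force_mN=force))
                k += 1
        times = np.sort([e.onset_s + 0.01 for e in evs if e.force_mN == 75.0])
        tr = make_train("u", times, 80.0)
        assert tuning.detect_threshold(tr, evs, seed=1) == 75.0

    def test_seed_required(self):
        evs = _events(10)
        tr = make_train("u", [1.0], 30.0)
        with pytest.raises(ValueError, match="seed"):
            tuning.detect_threshold(tr, evs, seed=None)

    def test_too_few_trials_rejected(self):
        evs = _events(5)
        tr = make_train("u", [1.0], 15.0)
        with pytest.raises(ValueError, match="need >= 10"):
            tuning.detect_threshold(tr, evs, seed=1)

    def test_recovery_monotone_in_effect_size(self):
        # recovery at A_on = 30 Hz must not fall below A_on = 10 Hz
        proto = ProtocolSpec(trials_per_force=20, brush_dur_s=0.0)
        rates = {}
        for a_on in (10.0, 30.0):
            pop = PopulationSpec(
                n_units=12, baseline_hz=3.0, threshold_mN=10.0, a_on_hz=a_on,
                a_sus_hz=0.0, a_off_hz=0.0, p_event=0.0, event_rate_on_hz=0,
                event_rate_sustained_hz=0, event_rate_off_hz=0, gain_cv=0.0,
                rho_tuning=1.0, force_first_spike=False)
            sess, _ = simulate_session(proto, pop, seed=17)
            evs = sess.events_of("indentation")
            th = [tuning.detect_threshold(t, evs, n_boot=300, seed=3)
                  for t, _ in sess.units]
            rates[a_on] = np.mean([t == 10.0 for t in th])
        assert rates[30.0] >= rates[10.0]


class TestBrushMaxRates:
    def _brush(self, dur=180.0, onset=0.0):
        return StimulusEvent("brush", onset, onset + dur, 0)

    def test_single_burst_minute_maxima(self):
        # 1 s burst at 100 Hz in minute 2 of 3, else silent
        ev = self._brush(180.0)
        burst = 70.0 + np.arange(100) * 0.01
        tr = make_train("u", burst, 200.0)
        res = tuning.brush_max_rates(tr, ev)
        np.testing.assert_allclose(res.minute_max_hz, [0.0, 100.0, 0.0])
        assert res.mean_max_hz == pytest.approx(100.0 / 3, rel=1e-6)

    def test_constant_poisson_maxima_within_extreme_band(self):
        rng = np.random.default_rng(3)
        dur = 180.0
        times = np.sort(rng.uniform(0, dur, int(20 * dur)))
        times = times[np.concatenate([[True], np.diff(times) > 1e-4])]
        tr = make_train("u", times, dur + 1)
        res = tuning.brush_max_rates(tr, self._brush(dur))
        # extreme-bin oracle: the max over 600 Poisson(2) bins stays below
        # the 0.01/600 upper tail quantile
        from scipy.stats import poisson

        bound = poisson.isf(0.01 / 600, 20 * 0.1) / 0.1
        assert np.all(res.minute_max_hz <= bound)

    def test_silent_unit_excluded_with_reason(self):
        evs = _events(20, period=2.5)
        onset = evs[-1].offset_s + 1.0
        rng = np.random.default_rng(4)
        base = np.sort(rng.uniform(0, onset, 200))
        tr = make_train("u", base, onset + 130.0)
        res = tuning.brush_max_rates(tr, self._brush(120.0, onset),
                                     baseline_events=evs, seed=5)
        assert not res.included
        assert "baseline" in res.reason

    def test_short_epoch_rejected(self):
        tr = make_train("u", [1.0], 100.0)
        with pytest.raises(ValueError, match="minute"):
            tuning.brush_max_rates(tr, self._brush(30.0))
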