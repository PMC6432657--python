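import numpy as np
import pytest

from ppgrhythms import coherence, preprocess, synth
from ppgrhythms.coherence import (autocorr, circular_median_deg,
                                  coherence_summary, coherence_threshold,
                                  dpss, mt_coherence, n_band_bins, xcorr)
from ppgrhythms.core import TimeSeries
from conftest import sine_ts


def _noise(n, rate, seed):
    return TimeSeries(np.random.default_rng(seed).normal(size=n), rate)


class TestDpss:
    def test_orthonormality_and_concentration_ordering(self):
        ts = dpss(1200, 10.0, 19)
        gram = ts.tapers @ ts.tapers.T
        np.testing.assert_allclose(gram, np.eye(19), atol=1e-8)
        assert np.all(np.diff(ts.eigenvalues) < 1e-12)
        assert np.all((ts.eigenvalues > 0) & (ts.eigenvalues <= 1.0 + 1e-12))

    def test_last_taper_still_concentrated(self):
        ts = dpss(1200, 10.0, 19)
        assert ts.eigenvalues[-1] > 0.5

    def test_taper_count_limit(self):
        with pytest.raises(ValueError, match="2\\*NW-1"):
            dpss(1200, 10.0, 25)


class TestMtCoherence:
    def test_self_coherence_is_one_with_zero_phase(self):
        x = _noise(3000, 10.0, 0)
        res = mt_coherence(x, x, window_s=120.0, step_s=60.0)
        assert np.all(res.magnitude > 1.0 - 1e-9)
        ph = res.phase_deg % 360.0
        assert np.all(np.minimum(ph, 360.0 - ph) < 1e-6)

    def test_magnitude_bounded_and_scale_invariant(self):
        x = _noise(3000, 10.0, 1)
        y = _noise(3000, 10.0, 2)
        res = mt_coherence(x, y, window_s=120.0, step_s=60.0)
        assert np.all(res.magnitude >= 0.0)
        assert np.all(res.magnitude <= 1.0 + 1e-9)
        scaled = mt_coherence(x, y.copy_with(samples=7.0 * y.samples),
                              window_s=120.0, step_s=60.0)
        np.testing.assert_allclose(scaled.magnitude, res.magnitude,
                                   atol=1e-10)

    def test_phase_sign_convention(self):
        # delaying y by tau yields phase +360 f tau (mod 360)
        x = preprocess.lowpass(_noise(6000, 10.0, 3), 2.0)
        tau, rate = 0.4, 10.0
        shift = int(tau * rate)
        y = x.copy_with(samples=np.concatenate(
            [np.zeros(shift), x.samples[:-shift]]))
        res = mt_coherence(x, y, window_s=120.0, step_s=120.0,
                           band=(0.2, 1.8))
        strong = (res.freqs > 0.3) & (res.freqs < 1.5)
        for i in range(res.window_times.size):
            expect = (360.0 * res.freqs[strong] * tau) % 360.0
            got = res.phase_deg[i, strong]
            diff = np.abs(got - expect)
            diff = np.minimum(diff, 360.0 - diff)
            assert np.percentile(diff, 90) < 10.0

    def test_independent_noise_rarely_beats_bonferroni_threshold(self):
        x = _noise(60_000, 10.0, 4)
        y = _noise(60_000, 10.0, 5)
        res = mt_coherence(x, y, window_s=120.0, step_s=120.0)
        c = coherence_threshold(0.05, 19, n_band_bins(res))
        assert np.mean(res.peak_coherence < c) >= 0.9

    def test_null_exceedance_rate_calibrated(self):
        # at a fixed frequency the theoretical level C(alpha, K, 1) is
        # exceeded at about the nominal rate on independent noise
        x = _noise(1_200_000, 10.0, 6)
        y = _noise(1_200_000, 10.0, 7)
        res = mt_coherence(x, y, window_s=120.0, step_s=120.0)
        c = coherence_threshold(0.05, 19, 1)
        j = int(np.argmin(np.abs(res.freqs - 1.0)))
        rate = np.mean(res.magnitude[:, j] > c)
        assert res.window_times.size >= 1000
        assert rate <= 1.5 * 0.05

    def test_zero_variance_window_flagged(self):
        x = TimeSeries(np.concatenate([np.zeros(1200),
                                       np.random.default_rng(8).normal(
                                           size=1200)]), 10.0)
        y = _noise(2400, 10.0, 9)
        res = mt_coherence(x, y, window_s=120.0, step_s=120.0)
        assert not res.valid[0]
        assert res.valid[1]


class TestThreshold:
    def test_vanishing_confidence_limit(self):
        assert coherence_threshold(1.0 - 1e-12, 19, 1) == pytest.approx(
            0.0, abs=1e-5)

    def test_published_configuration_value(self):
        # dof = 38, single comparison
        assert coherence_threshold(0.05, 19, 1) == pytest.approx(0.3915,
                                                                 abs=5e-4)

    def test_monotonicities(self):
        base = coherence_threshold(0.05, 19, 1)
        assert coherence_threshold(0.05, 19, 100) > base
        assert coherence_threshold(0.05, 30, 1) < base

    def test_invalid_dof_rejected(self):
        with pytest.raises(ValueError):
            coherence_threshold(0.05, 1, 1)


class TestSummary:
    def test_all_windows_significant(self, baseline_recording):
        rec, _ = baseline_recording
        h = preprocess.condition(rec.heart)
        py = preprocess.condition(rec.pyloric)
        res = mt_coherence(h, py, window_s=120.0, step_s=5.0)
        c = coherence_threshold(0.05, 19, n_band_bins(res))
        s = coherence_summary(res, c)
        assert s.fraction_significant > 0.5
        assert s.is_coherent_dataset

    def test_uncoupled_channels_not_flagged(self):
        # independent rhythms must wander (cycle jitter) for the coherence
        # null to hold: two near-perfect clocks are indistinguishable from
        # a coupled pair at finite analysis bandwidth
        p = synth.SynthParams(f_heart=1.1, f_pyloric=0.5, coupling=0.0,
                              noise_sd=0.1, cycle_jitter_sd=0.08,
                              duration_s=1800.0, seed=11)
        rec, _ = synth.gen_baseline(p)
        h = preprocess.condition(rec.heart)
        py = preprocess.condition(rec.pyloric)
        res = mt_coherence(h, py, window_s=120.0, step_s=5.0)
        c = coherence_threshold(0.05, 19, n_band_bins(res))
        s = coherence_summary(res, c)
        assert s.fraction_significant < 0.2
        assert not s.is_coherent_dataset

    def test_injected_phase_recovered(self, baseline_recording):
        rec, truth = baseline_recording
        h = preprocess.condition(rec.heart)
        py = preprocess.condition(rec.pyloric)
        res = mt_coherence(h, py, window_s=120.0, step_s=5.0)
        c = coherence_threshold(0.05, 19, n_band_bins(res))
        s = coherence_summary(res, c)
        diff = abs(s.median_phase_deg - truth.true_phase_offset_deg)
        assert min(diff, 360.0 - diff) <= 10.0


class TestCircularMedian:
    def test_handles_wraparound(self):
        angles = np.array([350.0, 355.0, 5.0, 10.0])
        m = circular_median_deg(angles)
        assert min(m, 360.0 - m) <= 10.0

    def test_plain_cluster(self):
        assert circular_median_deg(np.array([100.0, 110.0, 120.0])) == 110.0


class TestXcorr:
    def test_autocorrelation_at_zero_lag_is_one(self):
        x = _noise(5000, 10.0, 12)
        lags, ac = autocorr(x, 5.0)
        assert ac[lags == 0][0] == pytest.approx(1.0)

    def test_periodic_signal_peaks_at_multiples_of_period(self):
        x = sine_ts(0.5, 100.0, 10.0)
        lags, ac = autocorr(x, 4.0)
        peak_lags = lags[np.abs(ac) > 0.95]
        assert 0.0 in peak_lags
        assert np.any(np.isclose(peak_lags, 2.0, atol=0.1))

    def test_antiphase_channels_dip_near_zero_lag(self):
        x = sine_ts(1.1, 100.0, 10.0)
        y = sine_ts(1.1, 100.0, 10.0, phase=np.radians(190.0))
        lags, cc = xcorr(x, y, 2.0)
        trough = lags[np.argmin(cc)]
        assert abs(trough) < 0.1
        assert cc[lags == 0][0] < -0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            xcorr(TimeSeries(np.zeros(100), 10.0), _noise(100, 10.0, 0), 2.0)
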