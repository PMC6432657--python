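import numpy as np
import pytest
from statsmodels.regression.linear_model import burg as sm_burg

from ppgrhythms import preprocess, spectra, synth
from ppgrhythms.core import TimeSeries
from ppgrhythms.spectra import (ARModel, ar_line_powers, ar_psd,
                                baseline_median, burg_fit, default_order,
                                mode_track, population_histogram,
                                spectrogram, track_peak)
from conftest import make_ar


class TestBurgFit:
    def test_white_noise_has_no_structure(self):
        rng = np.random.default_rng(0)
        m = burg_fit(rng.normal(size=10_000), 4)
        assert np.all(np.abs(m.coeffs) < 0.1)

    def test_ar1_coefficient_recovery(self):
        x = make_ar([0.8], 100_000, seed=1)
        m = burg_fit(x, 1)
        assert m.coeffs[0] == pytest.approx(0.8, abs=0.01)
        assert m.sigma2 == pytest.approx(1.0, rel=0.05)

    def test_agrees_with_independent_burg_implementation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=512)
        for order in (1, 5, 33):
            mine = burg_fit(x, order)
            ref_coeffs, ref_s2 = sm_burg(x, order, demean=False)
            np.testing.assert_allclose(mine.coeffs, ref_coeffs, atol=1e-8)
            # sigma2 normalization conventions differ slightly
            assert mine.sigma2 == pytest.approx(ref_s2, rel=0.05)

    def test_default_order_for_standard_window(self):
        assert default_order(128) == 33

    def test_fitted_models_are_stable(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=128) + np.sin(
                2 * np.pi * rng.uniform(0.5, 2) * np.arange(128) / 10)
            assert burg_fit(x, 33).is_stable()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            burg_fit(np.zeros(100), 4)
        with pytest.raises(ValueError):
            burg_fit(np.ones(5), 10)


class TestArPsd:
    def test_order_zero_gives_flat_white_spectrum(self):
        m = ARModel(coeffs=np.zeros(0), sigma2=2.0)
        _, p = ar_psd(m, rate=10.0, n_freq=64)
        np.testing.assert_allclose(p, 2.0 / 10.0)

    def test_ar2_pole_places_the_peak(self):
        r, f0, rate = 0.95, 1.0, 10.0
        th = 2 * np.pi * f0 / rate
        m = ARModel(coeffs=np.array([2 * r * np.cos(th), -r * r]), sigma2=1.0)
        f, p = ar_psd(m, rate, n_freq=1024, fmax=5.0)
        assert f[np.argmax(p)] == pytest.approx(f0, abs=5.0 / 1023 + 0.01)

    def test_psd_integral_matches_process_variance(self):
        x = make_ar([0.8], 100_000, seed=4)
        m = burg_fit(x, 1)
        f, p = ar_psd(m, rate=1.0, n_freq=4096)
        # two-sided convention: [0, Nyquist] holds half the variance
        assert np.trapezoid(p, f) == pytest.approx(np.var(x) / 2, rel=0.05)
        assert np.all(p > 0)

    def test_line_power_decomposition_sums_to_variance(self):
        x = make_ar([1.2, -0.9, 0.1], 50_000, seed=5)
        m = burg_fit(x, 12)
        lines = ar_line_powers(m, rate=1.0)
        # complex pairs plus real poles carry the whole variance; the
        # pair subtotal must not exceed it
        assert sum(pw for _, pw in lines) <= np.var(x) * 1.05
        f_peak = max(lines, key=lambda t: t[1])[0]
        f, p = ar_psd(m, 1.0, 4096)
        assert f_peak == pytest.approx(f[np.argmax(p)], abs=0.01)


class TestSpectrogram:
    def test_window_count_arithmetic(self):
        ts = TimeSeries(np.random.default_rng(0).normal(size=3000), 10.0)
        spec = spectrogram(ts)   # 300 s: (300-12.8)/6.4 + 1 = 45 windows
        assert spec.window_times.size == 45

    def test_steady_rhythm_tracked_against_ground_truth(self):
        p = synth.SynthParams(f_heart=1.1, coupling=0.0, noise_sd=0.05,
                              duration_s=300.0, seed=2)
        rec, truth = synth.gen_baseline(p)
        h = preprocess.condition(rec.heart)
        spec = spectrogram(h)
        tr = track_peak(spec, (0.2, 2.5))
        half = 6.4
        t_true = np.array([
            truth.f_heart_inst[max(int((tc - half) * 500), 0):
                               int((tc + half) * 500)].mean()
            for tc in tr.window_times])
        err = np.abs(tr.peak_freq - t_true)
        assert np.mean(err <= 0.05) >= 0.95
        binw = spec.freqs[1] - spec.freqs[0]
        assert abs(np.median(tr.peak_freq) - 1.1) <= 2 * binw

    def test_noise_windows_never_form_a_stable_band(self):
        rng = np.random.default_rng(0)
        noise = spectrogram(TimeSeries(rng.normal(size=3000), 10.0))
        t = np.arange(3000) / 10.0
        rhythm = spectrogram(TimeSeries(
            np.sin(2 * np.pi * 0.6 * t) + 0.05 * rng.normal(size=3000), 10.0))
        noise_ratio = noise.power.max(axis=1) / np.median(noise.power, axis=1)
        rhythm_ratio = rhythm.power.max(axis=1) / np.median(rhythm.power,
                                                            axis=1)
        assert noise_ratio.max() < 50
        assert rhythm_ratio.min() > 1000

    def test_concatenation_matches_on_aligned_windows(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2560)
        full = spectrogram(TimeSeries(x, 10.0))
        a = spectrogram(TimeSeries(x[:1280], 10.0))
        b = spectrogram(TimeSeries(x[1280:], 10.0, t0=128.0))
        np.testing.assert_allclose(a.power, full.power[:19])
        np.testing.assert_allclose(b.power, full.power[20:])

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            spectrogram(TimeSeries(np.ones(64), 10.0))


class TestTracking:
    def test_single_sine_gives_constant_track(self):
        t = np.arange(3000) / 10.0
        rng = np.random.default_rng(0)
        ts = TimeSeries(np.sin(2 * np.pi * 0.8 * t)
                        + 0.05 * rng.normal(size=3000), 10.0)
        tr = track_peak(spectrogram(ts), (0.2, 2.5))
        assert np.ptp(tr.peak_freq) < 0.06

    def test_band_selects_the_requested_rhythm(self):
        t = np.arange(3000) / 10.0
        rng = np.random.default_rng(0)
        two = (np.sin(2 * np.pi * 0.5 * t) + np.sin(2 * np.pi * 1.2 * t)
               + 0.05 * rng.normal(size=3000))
        tr = track_peak(spectrogram(TimeSeries(two, 10.0)), (0.9, 2.0))
        assert np.median(tr.peak_freq) == pytest.approx(1.2, abs=0.05)

    def test_tie_breaks_toward_lower_frequency(self):
        spec = spectra.Spectrogram(np.array([0.0]), np.linspace(0, 5, 11),
                                   np.ones((1, 11)))
        tr = track_peak(spec, (0.5, 4.5))
        assert tr.peak_freq[0] == pytest.approx(0.5)

    def test_empty_band_rejected(self):
        spec = spectra.Spectrogram(np.array([0.0]), np.linspace(0, 5, 11),
                                   np.ones((1, 11)))
        with pytest.raises(ValueError):
            track_peak(spec, (4.6, 4.9))

    def test_mode_track_resolves_harmonic_rich_waveform(self):
        # the two-harmonic pyloric waveform defeats naive density argmax
        # in a fraction of windows; line-power tracking must not
        p = synth.SynthParams(f_pyloric=0.6, coupling=0.0, noise_sd=0.05,
                              duration_s=300.0, seed=4)
        rec, truth = synth.gen_baseline(p)
        py = preprocess.condition(rec.pyloric)
        tr = mode_track(py)
        t_true = np.array([
            truth.f_pyloric_inst[max(int((tc - 6.4) * 500), 0):
                                 int((tc + 6.4) * 500)].mean()
            for tc in tr.window_times])
        assert np.all(np.abs(tr.peak_freq - t_true) < 0.1)

    def test_median_smoothing_removes_isolated_outliers(self):
        tr = spectra.FrequencyTrack(np.arange(9.0),
                                    np.array([.6, .6, .6, 1.2, .6, .6, .6,
                                              .6, .6]),
                                    np.ones(9))
        sm = tr.median_smoothed(5)
        np.testing.assert_allclose(sm.peak_freq, 0.6)


class TestSummaries:
    def test_baseline_median(self):
        tr = spectra.FrequencyTrack(np.arange(3.0),
                                    np.array([0.5, 0.5, 2.0]), np.ones(3))
        assert baseline_median(tr) == 0.5
        const = spectra.FrequencyTrack(np.arange(4.0), np.full(4, 1.1),
                                       np.ones(4))
        assert baseline_median(const) == 1.1

    def test_population_histogram_normalization(self):
        edges, h = population_histogram([[1.0, 1.0, 1.0]], 0.5)
        assert h.sum() == pytest.approx(1.0)
        assert h.max() == pytest.approx(1.0)
        edges, h = population_histogram([[0.3], [1.3]], 0.5)
        assert sorted(h[h > 0]) == pytest.approx([0.5, 0.5])
        rng = np.random.default_rng(0)
        animals = [rng.uniform(0.0, 2.4, rng.integers(5, 50))
                   for _ in range(49)]
        _, h = population_histogram(animals, 0.1, freq_range=(0.0, 2.5))
        assert h.sum() <= 1.0 + 1e-12
        assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_mass_reduces_total(self):
        _, h = population_histogram([[0.5, 3.0]], 0.5, freq_range=(0.0, 2.5))
        assert h.sum() == pytest.approx(0.5)
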