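import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qeegnorm.montage import BipolarRecording
from qeegnorm.spectral import (BAND_NAMES, DEFAULT_BANDS, WindowedSpectrum,
                               band_areas, log_transform, make_windows,
                               n_windows_expected, power_spectrum,
                               spectral_entropy)

FS = 128.0


def bip(samples, fs=FS):
    samples = np.atleast_2d(samples)
    chans = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return BipolarRecording(chans, samples, fs)


def sine(freq, duration=10.0, fs=FS, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


class TestWindows:
    @pytest.mark.parametrize("duration,expected", [(1, 1), (10, 11), (180, 199)])
    def test_count_formula(self, duration, expected):
        assert n_windows_expected(duration) == expected

    def test_count_matches_bruteforce_sweep(self):
        # brute-force enumeration of 1-s windows stepping 0.9 s
        for T in list(np.arange(1.0, 30.01, 0.35)) + [120.0, 180.0, 300.0]:
            count, i = 0, 0
            while i * 0.9 + 1.0 <= T + 1e-9:
                count += 1
                i += 1
            assert n_windows_expected(T) == count, T

    def test_windows_fit_inside_record(self):
        rec = bip(sine(10, duration=10.0))
        ws = make_windows(rec)
        assert ws.n_windows == 11
        assert ws.starts[-1] + ws.n_samples <= rec.n_times
        np.testing.assert_array_equal(
            ws.data[3, 0], rec.samples[0, ws.starts[3]:ws.starts[3] + 128])

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            make_windows(bip(sine(10, duration=0.5)))


class TestPowerSpectrum:
    def test_grid_spacing_half_hz(self):
        spec = power_spectrum(make_windows(bip(sine(10))))
        assert spec.df == pytest.approx(0.5)
        assert spec.freqs[0] == 0.0
        assert np.allclose(np.diff(spec.freqs), 0.5)

    def test_parseval_every_window(self, rng):
        x = rng.standard_normal((3, int(10 * FS)))
        ws = make_windows(bip(x))
        for taper in ("hann", "rect"):
            spec = power_spectrum(ws, taper=taper)
            areas = spec.S.sum(axis=2) * spec.df
            msq = np.mean(ws.data ** 2, axis=2)
            assert np.max(np.abs(areas / msq - 1)) < 0.01

    def test_sine_line_native_resolution(self):
        # at native 1 Hz bins with a rectangular taper an integral-frequency
        # sine is a single spectral line
        ws = make_windows(bip(sine(10)))
        spec = power_spectrum(ws, taper="rect", pad_factor=1)
        mean = spec.mean_spectrum()[0]
        inband = (spec.freqs >= 0.5) & (spec.freqs <= 30)
        peak = mean[spec.freqs == 10.0].sum()
        assert peak / mean[inband].sum() > 0.99

    def test_sine_line_default_config(self):
        ws = make_windows(bip(sine(10)))
        spec = power_spectrum(ws)
        mean = spec.mean_spectrum()[0]
        assert spec.freqs[np.argmax(mean)] == pytest.approx(10.0)
        ba = band_areas(spec).areas.iloc[0]
        assert ba["alpha"] / ba.sum() > 0.95

    def test_white_noise_flat_within_sampling_error(self, rng):
        x = rng.standard_normal(int(120 * FS))
        spec = power_spectrum(make_windows(bip(x)))
        mean = spec.mean_spectrum()[0]
        inband = (spec.freqs >= 0.5) & (spec.freqs <= 30)
        rel = mean[inband] / mean[inband].mean()
        # ~133 windows averaged; chi-squared bound with generous slack
        assert np.all(np.abs(rel - 1) < 6 / np.sqrt(spec.S.shape[0]))

    def test_nonfinite_input_rejected(self):
        x = sine(10)
        x[5] = np.inf
        with pytest.raises(ValueError, match="finite"):
            power_spectrum(make_windows(bip(x)))


class TestBandAreas:
    def test_partition_is_exact(self, rng):
        x = rng.standard_normal((2, int(20 * FS)))
        spec = power_spectrum(make_windows(bip(x)))
        ba = band_areas(spec)
        total_mask = (spec.freqs >= 0.5) & (spec.freqs <= 30.0)
        total = (spec.S[:, :, total_mask].sum(axis=2) * spec.df).mean(axis=0)
        np.testing.assert_allclose(ba.areas.sum(axis=1).to_numpy(), total,
                                   rtol=1e-10)

    def test_pure_alpha_sine(self):
        ba = band_areas(power_spectrum(make_windows(bip(sine(10))))).areas
        assert ba.loc["ch0", "alpha"] / ba.loc["ch0"].sum() > 0.98
        for b in ("delta", "theta", "beta"):
            assert ba.loc["ch0", b] < 0.01 * ba.loc["ch0"].sum()

    def test_amplitude_ratio_between_bands(self):
        x = sine(2.0, duration=30.0) + sine(20.0, duration=30.0, amplitude=2.0)
        ba = band_areas(power_spectrum(make_windows(bip(x)))).areas
        assert ba.loc["ch0", "beta"] / ba.loc["ch0", "delta"] == pytest.approx(
            4.0, rel=0.1)

    def test_band_edge_outside_grid_rejected(self):
        spec = power_spectrum(make_windows(bip(sine(10))))
        with pytest.raises(ValueError, match="outside"):
            band_areas(spec, {"fast": (30.0, 100.0)})


class TestLogTransform:
    def test_log10_identities(self):
        import pandas as pd

        areas = pd.DataFrame({"alpha": [10.0, 1.0]}, index=["a", "b"])
        out = log_transform(areas)
        assert out.loc["a", "alpha"] == pytest.approx(1.0)
        assert out.loc["b", "alpha"] == pytest.approx(0.0)
        np.testing.assert_allclose(10.0 ** out.to_numpy(), areas.to_numpy())

    def test_rejects_nonpositive(self):
        import pandas as pd

        with pytest.raises(ValueError, match="positive"):
            log_transform(pd.DataFrame({"alpha": [0.0]}))


def flat_spectrum(n_windows=3, n_channels=2):
    freqs = np.arange(0, 64.1, 0.5)
    S = np.ones((n_windows, n_channels, freqs.size))
    return WindowedSpectrum(S, freqs, tuple(f"ch{i}" for i in range(n_channels)))


class TestSpectralEntropy:
    def test_flat_spectrum_is_maximal(self):
        ev = spectral_entropy(flat_spectrum())
        assert ev.n_bins == 60
        np.testing.assert_allclose(ev.sse.to_numpy(), np.log2(60), rtol=1e-12)

    def test_single_line_is_zero(self):
        spec = flat_spectrum()
        spec.S[:] = 0.0
        spec.S[:, :, 20] = 5.0
        ev = spectral_entropy(spec)
        np.testing.assert_allclose(ev.sse.to_numpy(), 0.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        freqs = np.arange(0, 64.1, 0.5)
        S = rng.uniform(0.1, 5.0, size=(4, 2, freqs.size))
        a = spectral_entropy(WindowedSpectrum(S, freqs, ("a", "b")))
        b = spectral_entropy(WindowedSpectrum(S * 123.4, freqs, ("a", "b")))
        np.testing.assert_allclose(a.sse.to_numpy(), b.sse.to_numpy())

    def test_decreases_under_progressive_concentration(self):
        freqs = np.arange(0, 64.1, 0.5)
        support = (freqs >= 0.5) & (freqs <= 30.0)
        idx = np.flatnonzero(support)
        last = np.inf
        for k in (60, 30, 10, 3, 1):
            S = np.zeros((1, 1, freqs.size))
            S[0, 0, idx[:k]] = 1.0
            sse = spectral_entropy(WindowedSpectrum(S, freqs, ("a",))).sse.iloc[0]
            assert sse < last
            last = sse

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_hold_for_random_spectra(self, seed):
        g = np.random.default_rng(seed)
        freqs = np.arange(0, 64.1, 0.5)
        S = g.exponential(1.0, size=(2, 1, freqs.size))
        sse = spectral_entropy(WindowedSpectrum(S, freqs, ("a",))).sse.iloc[0]
        assert 0.0 <= sse <= np.log2(60) + 1e-9

    def test_mean_spectrum_method_at_least_per_window(self, rng):
        x = rng.standard_normal(int(20 * FS))
        spec = power_spectrum(make_windows(bip(x)))
        per_win = spectral_entropy(spec, method="per-window").sse.iloc[0]
        pooled = spectral_entropy(spec, method="mean-spectrum").sse.iloc[0]
        # entropy is concave: the mean spectrum is at least as flat
        assert pooled >= per_win - 1e-9

    def test_all_zero_spectrum_rejected(self):
        spec = flat_spectrum()
        spec.S[:] = 0.0
        with pytest.raises(ValueError, match="zero"):
            spectral_entropy(spec)
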