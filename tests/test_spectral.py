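import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from piva import events as ev
from piva import io as pio
from piva import spectral as sp
from piva import synthetic_data as syn

FS = 1000.0
N = 8192


def sine(amplitude, freq, n=N, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def dirichlet_amplitude(amplitude, freq, k, n=N, fs=FS):
    """Closed-form single-sided amplitude at bin k of a pure sine.

    Independent oracle: geometric-series evaluation of the DFT of
    ``A sin(2 pi f t)``, no FFT involved.  Mean subtraction does not affect
    non-DC bins (the DFT of a constant is zero off bin 0 over full periods
    of the exponential), so it is not modelled.
    """

    def geom(theta):
        if abs(theta) < 1e-15:
            return complex(n)
        return (np.exp(1j * theta * n) - 1.0) / (np.exp(1j * theta) - 1.0)

    theta_p = 2 * np.pi * (freq / fs - k / n)
    theta_m = 2 * np.pi * (-freq / fs - k / n)
    x_k = amplitude / 2j * (geom(theta_p) - geom(theta_m))
    return 2.0 * abs(x_k) / n


class TestSegmentWindows:
    def test_80000_samples_nine_windows(self):
        wins = sp.segment_windows(np.zeros(80_000), 8192)
        assert len(wins) == 9

    def test_incomplete_window_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            wins = sp.segment_windows(np.zeros(8191), 8192)
        assert wins == []

    def test_half_hop(self):
        x = np.arange(16_384)
        wins = sp.segment_windows(x, 8192, hop=4096)
        assert len(wins) == 3
        assert [w[0] for w in wins] == [0, 4096, 8192]

    def test_trailing_partial_discarded(self):
        wins = sp.segment_windows(np.zeros(10_000), 8192)
        assert len(wins) == 1
        assert len(wins[0]) == 8192

    @pytest.mark.parametrize("kwargs", [{"window_length": 1}, {"hop": 0}, {"hop": 9000}])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            sp.segment_windows(np.zeros(20_000), **{"window_length": 8192, **kwargs})


class TestAmplitudeSpectrum:
    def test_exact_bin_sinusoid_recovered(self):
        f = 32 * FS / N  # integer cycles
        spec = sp.compute_amplitude_spectrum(sine(5.0, f), FS)
        assert spec.amplitudes[32] == pytest.approx(5.0, rel=1e-9)
        assert spec.frequencies[32] == pytest.approx(f)

    def test_constant_signal_all_zero(self):
        spec = sp.compute_amplitude_spectrum(np.full(N, 17.0), FS)
        np.testing.assert_allclose(spec.amplitudes[1:], 0.0, atol=1e-9)

    def test_offset_does_not_leak(self):
        # mean subtraction: a large DC offset leaves tone bins untouched
        f = 32 * FS / N
        spec = sp.compute_amplitude_spectrum(sine(5.0, f) + 500.0, FS)
        assert spec.amplitudes[32] == pytest.approx(5.0, rel=1e-9)

    def test_grid_spacing(self):
        spec = sp.compute_amplitude_spectrum(np.random.default_rng(0).normal(size=N), FS)
        assert spec.bin_width == pytest.approx(FS / N)

    def test_nan_rejected(self):
        x = sine(1.0, 10.0)
        x[100] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            sp.compute_amplitude_spectrum(x, FS, window_start=2.5)

    def test_scalloping_matches_dirichlet_oracle(self):
        # 200/min tone between bins: worst realistic leakage case
        amplitude, freq = 5.0, 200.0 / 60.0
        k = int(round(freq * N / FS))  # nearest bin, 27
        expected = dirichlet_amplitude(amplitude, freq, k)
        spec = sp.compute_amplitude_spectrum(sine(amplitude, freq), FS)
        assert spec.amplitudes[k] == pytest.approx(expected, rel=1e-6)
        # rectangular-taper scalloping: worst case is 2/pi at half-bin offset
        assert 2 / np.pi * amplitude <= spec.amplitudes[k] <= amplitude

    def test_worst_case_half_bin_offset_within_scalloping_bound(self):
        amplitude = 5.0
        freq = (27 + 0.5) * FS / N  # exactly between bins
        spec = sp.compute_amplitude_spectrum(sine(amplitude, freq), FS)
        for k in (27, 28):
            expected = dirichlet_amplitude(amplitude, freq, k)
            assert spec.amplitudes[k] == pytest.approx(expected, rel=1e-6)

    def test_hann_taper_compensated(self):
        f = 32 * FS / N
        spec = sp.compute_amplitude_spectrum(sine(5.0, f), FS, taper="hann")
        assert spec.amplitudes[32] == pytest.approx(5.0, rel=1e-3)

    def test_parseval_identity(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=N)
        x -= x.mean()
        spec = sp.compute_amplitude_spectrum(x, FS)
        amps = spec.amplitudes
        nyq = len(amps) - 1
        lhs = float(np.sum(x**2))
        rhs = N / 2.0 * float(np.sum(amps[1:nyq] ** 2)) + N * (
            amps[0] ** 2 + amps[nyq] ** 2
        )
        assert rhs == pytest.approx(lhs, rel=1e-6)

    @given(k=hst.integers(5, 1000), amplitude=hst.floats(0.1, 100))
    @settings(max_examples=20, deadline=None)
    def test_exact_bin_recovery_property(self, k, amplitude):
        spec = sp.compute_amplitude_spectrum(sine(amplitude, k * FS / N), FS)
        assert spec.amplitudes[k] == pytest.approx(amplitude, rel=1e-9)


class TestDominantFrequency:
    def test_compression_train_200_per_min(self):
        x = syn.generate_compression_train(200, N / FS, FS)
        spec = sp.compute_amplitude_spectrum(x, FS)
        freq = sp.find_dominant_frequency(spec, (2.0, 5.0))
        assert abs(freq - 200 / 60) <= FS / N  # within one bin (0.122 Hz)
        assert round(freq, 1) == 3.3

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.arange(10) * 1.0
        amps = np.zeros(10)
        amps[[3, 7]] = 5.0
        spec = sp.SpectrumWindow(0.0, 10, freqs, amps)
        assert sp.find_dominant_frequency(spec, (0.5, 9.0)) == 3.0

    def test_band_restriction_absolute(self):
        x = sine(10.0, 32 * FS / N) + sine(1.0, 64 * FS / N)
        spec = sp.compute_amplitude_spectrum(x, FS)
        # band excludes the 10x larger tone at bin 32
        freq = sp.find_dominant_frequency(spec, (7.0, 9.0))
        assert freq == pytest.approx(64 * FS / N)

    def test_empty_band_rejected(self):
        spec = sp.compute_amplitude_spectrum(sine(1.0, 10.0), FS)
        with pytest.raises(ValueError, match="no frequency bins"):
            sp.find_dominant_frequency(spec, (3.00001, 3.00002))

    def test_inverted_band_rejected(self):
        spec = sp.compute_amplitude_spectrum(sine(1.0, 10.0), FS)
        with pytest.raises(ValueError, match="lo < hi"):
            sp.find_dominant_frequency(spec, (5.0, 2.0))


class TestExtractPiva:
    def test_constant_envelope_exact_bin(self, calibration_recording):
        cfg, rec, _, amp = calibration_recording
        series = sp.extract_piva(rec, "tail_venous")
        fully_inside = [
            i for i, t in enumerate(series.times)
            if t - N / FS / 2 >= cfg.cpr_start and t + N / FS / 2 <= cfg.rosc_time
        ]
        assert len(fully_inside) >= 5
        np.testing.assert_allclose(series.values[fully_inside], amp, rtol=1e-6)

    def test_rms_oracle_equivalence(self, calibration_recording):
        # PIVA == sqrt(2) x windowed RMS for a pure in-CPR tone
        cfg, rec, _, amp = calibration_recording
        series = sp.extract_piva(rec, "tail_venous")
        samples = rec.channel("tail_venous")
        w0 = 2 * 8192  # window fully inside CPR
        win = samples[w0 : w0 + 8192]
        win = win - win.mean()
        # remove the exact-bin ventilation tone before the RMS comparison
        t = np.arange(8192) / FS
        vent_f = cfg.ventilation_rate / 60.0
        c = 2 / 8192 * np.sum(win * np.exp(-2j * np.pi * vent_f * t))
        win = win - (c.real * np.cos(2 * np.pi * vent_f * t)
                     - c.imag * np.sin(2 * np.pi * vent_f * t))
        rms = np.sqrt(np.mean(win**2))
        k = w0 // 8192
        assert series.values[k] == pytest.approx(np.sqrt(2) * rms, rel=1e-6)

    def test_amplitude_linearity(self, calibration_recording):
        cfg, rec, _, _ = calibration_recording
        scaled = pio.Recording(
            channel_names=rec.channel_names,
            samples=rec.samples * 3.0,
            sampling_rate=rec.sampling_rate,
            annotations=rec.annotations,
            channel_kinds=rec.channel_kinds,
        )
        s1 = sp.extract_piva(rec, "tail_venous")
        s3 = sp.extract_piva(scaled, "tail_venous")
        np.testing.assert_allclose(s3.values, 3.0 * s1.values, rtol=1e-9)

    def test_time_shift_robustness(self):
        # shifting by an integer number of compression periods moves PIVA < 1%
        rate, amp = 200.0, 4.0
        period = int(FS * 60 / rate)  # 300 samples
        n_total = 60_000
        x = amp * np.sin(2 * np.pi * (rate / 60) * np.arange(n_total + period) / FS)
        ann = pio.Annotations(0.0, n_total / FS, rate)

        def rec_of(samples):
            return pio.Recording(["v"], samples[None, :n_total], FS, ann, {"v": "venous"})

        s0 = sp.extract_piva(rec_of(x), "v")
        s1 = sp.extract_piva(rec_of(x[period:]), "v")
        np.testing.assert_allclose(s1.values, s0.values, rtol=0.01)

    def test_unimodal_series_tracks_rms_oracle(self):
        # exact-bin carrier so scalloping cannot bias the single-bin value;
        # residual disagreement is envelope modulation within the window
        sites = {
            site: syn.SiteEnvelope(13.5, 9.0, 30.0, 10.0, 12.0)
            for site in ("tail", "femoral", "central")
        }
        cfg = syn.SimConfig(
            compression_rate=60.0 * 27 * FS / N,
            ventilation_rate=60.0 * 8 * FS / N,
            sites=sites,
        )
        rec, _ = syn.generate_recording(cfg)
        series = sp.extract_piva(rec, "central_venous", hop=2048)
        samples = rec.channel("central_venous")
        inside = series.in_cpr
        # windowed RMS x sqrt(2) oracle on the same windows, 10% agreement
        for i in np.nonzero(inside)[0]:
            start = i * 2048
            win = samples[start : start + 8192]
            win = win - win.mean()
            oracle = np.sqrt(2 * np.mean(win**2))
            # windows where compression dominates the ventilation ripple
            # (0.9 mmHg for the central site); boundary windows are skipped
            if oracle > 3.0:
                assert series.values[i] == pytest.approx(oracle, rel=0.10)

    def test_single_prominent_peak_no_secondary_maxima(self, default_recording):
        rec, truth = default_recording
        series = sp.extract_piva(rec, "femoral_venous", hop=1024)
        vals = series.values[series.in_cpr]
        peak = np.argmax(vals)
        # series rises to the peak and falls after it (one-window slack)
        assert np.all(np.diff(vals[: peak + 1]) > -0.05 * vals.max())
        assert np.all(np.diff(vals[peak:]) < 0.05 * vals.max())

    def test_six_windows_in_55s_cpr(self, default_recording):
        rec, _ = default_recording
        series = sp.extract_piva(rec, "tail_venous")
        ann = rec.annotations
        fully_in = np.sum(
            (series.times - N / FS / 2 >= ann.cpr_start)
            & (series.times + N / FS / 2 <= ann.rosc_time)
        )
        assert fully_in <= 6  # floor(55000 / 8192)

    def test_short_recording_empty_series(self):
        ann = pio.Annotations(0.0, 4.0, 200.0)
        rec = pio.Recording(["v"], np.zeros((1, 5000)), FS, ann, {"v": "venous"})
        with pytest.warns(UserWarning, match="shorter"):
            series = sp.extract_piva(rec, "v")
        assert len(series) == 0

    def test_non_venous_channel_warns(self, default_recording):
        rec, _ = default_recording
        with pytest.warns(UserWarning, match="venous"):
            sp.extract_piva(rec, "arterial")

    def test_out_of_cpr_windows_flagged(self, default_recording):
        rec, _ = default_recording
        series = sp.extract_piva(rec, "tail_venous")
        ann = rec.annotations
        for t, flag in zip(series.times, series.in_cpr):
            overlaps = (t + N / FS / 2 > ann.cpr_start) and (t - N / FS / 2 < ann.rosc_time)
            assert flag == overlaps

    def test_band_energy_variant_bounds_single_bin(self, default_recording):
        rec, _ = default_recording
        single = sp.extract_piva(rec, "central_venous")
        banded = sp.extract_piva(rec, "central_venous", band_energy=True)
        assert np.all(banded.values >= single.values - 1e-12)
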