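"""Filtering, R-peak detection, and stream alignment."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from pttbp.preprocess import (
    AlignmentError,
    FilterSpec,
    align_to_reference,
    bandpass_fir,
    design_bandpass,
    detect_r_peaks,
    estimate_lag,
    smooth_moving_average,
)

FS = 1000.0
PPG_BAND = FilterSpec(1.0, 8.0)


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass_fir(np.full(40000, 5.0), FS, PPG_BAND)
        interior = out[5000:-5000]
        assert np.max(np.abs(interior)) < 1e-3 * 5.0

    def test_passband_tone_within_1_db(self):
        t = np.arange(40000) / FS
        out = bandpass_fir(np.sin(2 * np.pi * 4.0 * t), FS, PPG_BAND)
        amp = np.max(np.abs(out[8000:32000]))
        assert abs(20 * np.log10(amp)) < 1.0
        # frequency-response oracle agrees
        taps = design_bandpass(PPG_BAND, FS)
        _, h = sp_signal.freqz(taps, worN=[4.0], fs=FS)
        assert abs(amp - np.abs(h[0])) < 0.01

    def test_stopband_tone_attenuated_20_db(self):
        t = np.arange(40000) / FS
        out = bandpass_fir(np.sin(2 * np.pi * 0.2 * t), FS, PPG_BAND)
        amp = np.max(np.abs(out[8000:32000]))
        assert -20 * np.log10(amp) >= 20.0

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=20000)
        k = 137
        y = bandpass_fir(x, FS, PPG_BAND)
        y_shift = bandpass_fir(np.roll(x, k), FS, PPG_BAND)
        np.testing.assert_allclose(y_shift[5000 + k : 15000 + k], y[5000:15000], atol=1e-9)

    def test_invalid_band_and_short_signal(self):
        with pytest.raises(ValueError):
            bandpass_fir(np.zeros(10000), FS, FilterSpec(8.0, 1.0))
        with pytest.raises(ValueError, match="length"):
            bandpass_fir(np.zeros(100), FS, PPG_BAND)


class TestMovingAverage:
    def test_constant_preserved(self):
        out = smooth_moving_average(np.full(500, 100.0), FS, 50)
        np.testing.assert_allclose(out, 100.0)

    def test_interior_impulse_spreads_to_window(self):
        x = np.zeros(500)
        x[250] = 1.0
        out = smooth_moving_average(x, FS, 50)
        assert np.sum(np.isclose(out, 1 / 50)) == 50
        assert out.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("freq", [7.0, 20.0])
    def test_sine_attenuation_matches_dirichlet_kernel(self, freq):
        t = np.arange(30000) / FS
        out = smooth_moving_average(np.sin(2 * np.pi * freq * t), FS, 50)
        measured = np.max(np.abs(out[1000:-1000]))
        n_win, period = 50, 1.0 / FS
        expected = abs(
            np.sin(np.pi * freq * n_win * period) / (n_win * np.sin(np.pi * freq * period))
        )
        assert measured == pytest.approx(expected, abs=2e-3)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_average(np.array([]), FS)


class TestRPeaks:
    def test_clean_60_bpm(self):
        t = np.arange(30000) / FS
        ecg = sum(np.exp(-0.5 * ((t - (0.5 + k)) / 0.008) ** 2) for k in range(30))
        r = detect_r_peaks(ecg, FS, raw=True)
        assert len(r) == 30
        assert np.allclose(np.diff(r), 1.0, atol=0.002)

    def test_noisy_simulator_ecg_matches_truth(self):
        from pttbp.simulate import NoiseModel, compact_schedule, default_law, simulate_session

        noise = NoiseModel(
            channel_noise_sd={"ecg_wearable": 0.1, "ecg_ref": 0.0, "scg_z": 0, "ppg": 0, "abp": 0},
            burst_rate_per_min=0.0,
            hr_sd_bpm=3.0,
        )
        session, rec = simulate_session(
            default_law(), noise, schedule=compact_schedule(20.0, tasks=("rest",)), seed=2
        )
        detected = detect_r_peaks(session.channel("ecg_wearable").samples, FS, raw=True)
        true_r = rec.beats["r_time_s"].to_numpy()
        matched = sum(np.min(np.abs(detected - r)) <= 0.010 for r in true_r)
        assert matched / len(true_r) >= 0.99

    def test_zero_noise_recovery_within_2_ms(self, small_session):
        session, rec = small_session
        detected = detect_r_peaks(session.channel("ecg_wearable").samples, FS, raw=True)
        for r in rec.beats["r_time_s"]:
            assert np.min(np.abs(detected - r)) <= 0.002

    def test_flat_signal_raises(self):
        with pytest.raises(ValueError, match="no peaks"):
            detect_r_peaks(np.zeros(20000), FS, raw=True)


class TestAlignment:
    def test_zero_lag_leaves_lengths(self, rng):
        from pttbp.simulate import NoiseModel, compact_schedule, default_law, simulate_session

        session, _ = simulate_session(
            default_law(), NoiseModel(), seed=3, lag_samples=0,
            schedule=compact_schedule(15.0, tasks=("sit_baseline", "rest")),
        )
        n_before = len(session.channel("abp").samples)
        aligned = align_to_reference(session)
        assert aligned.alignment_lag_samples == 0
        assert len(aligned.channel("abp").samples) == n_before

    def test_known_delay_recovered_and_trimmed(self, small_session):
        session, rec = small_session
        assert rec.lag_samples == 150
        n_before = len(session.channel("abp").samples)
        aligned = align_to_reference(session)
        assert aligned.alignment_lag_samples == 150
        assert len(aligned.channel("abp").samples) == n_before - 150
        lengths = {len(c.samples) for c in aligned.channels.values()}
        assert len(lengths) == 1

    def test_idempotent(self, small_session):
        session, _ = small_session
        twice = align_to_reference(align_to_reference(session))
        assert twice.alignment_lag_samples == 0

    def test_lag_estimate_robust_to_jitter(self, rng):
        """Monte Carlo: independent +/-1 ms detection jitter on both trains
        still recovers a 250-sample delay within one sample."""
        for _ in range(50):
            r = np.cumsum(rng.normal(0.857, 0.03, 60))
            n = int(r[-1] * FS) + 500
            r2 = r + 0.250 + rng.normal(0, 0.001, len(r))
            lag = estimate_lag(r + rng.normal(0, 0.001, len(r)), r2, FS, n)
            assert abs(lag - 250) <= 1

    def test_metronomic_rhythm_is_ambiguous(self):
        """With a perfectly periodic fast rhythm, competing lags one period
        apart fall inside the search window and must be flagged."""
        r = 0.5 + 0.4 * np.arange(200)  # 150 bpm, zero jitter
        n = int(r[-1] * FS) + 500
        with pytest.raises(AlignmentError, match="ambiguous"):
            estimate_lag(r, r + 0.05, FS, n)
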