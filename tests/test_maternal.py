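"""Maternal vitals: QRS detection, heart rate, SpO2, respiration, temperature."""

import numpy as np
import pytest

from mfv.core import BeatSeries, SensorStream, ValidationError
from mfv.maternal import (
    compute_spo2,
    detect_ppg_pulses,
    detect_r_peaks,
    hr_from_beats,
    respiratory_rate,
    temperature_series,
)
from mfv.simulate import ScenarioConfig, simulate_session, with_noise_snr

from conftest import match_events


class TestDetectRPeaks:
    def test_clean_60bpm_exact_count_and_timing(self):
        session, truth = simulate_session(
            ScenarioConfig(duration_s=60.0, maternal_hr_bpm=60.0, seed=1)
        )
        ecg = session.get("chest", "ecg")
        beats = detect_r_peaks(ecg)
        assert beats.n == truth.maternal_beat_ms.size == 60
        err = np.abs(beats.times_ms[:, None] - truth.maternal_beat_ms[None, :]).min(axis=1)
        assert err.max() <= ecg.dt_ms + 1e-9  # within one sample

    def test_flat_signal_empty_with_warning(self):
        ecg = SensorStream("ecg", "chest", 512.0, np.zeros(512 * 10))
        with pytest.warns(UserWarning, match="constant"):
            beats = detect_r_peaks(ecg)
        assert beats.n == 0

    def test_too_short_signal_rejected(self):
        ecg = SensorStream("ecg", "chest", 512.0, np.random.default_rng(0).normal(size=512))
        with pytest.raises(ValidationError):
            detect_r_peaks(ecg)

    def test_noisy_sensitivity_and_ppv(self):
        """At 10 dB SNR both sensitivity and PPV stay above 0.98."""
        session, truth = simulate_session(
            ScenarioConfig(duration_s=60.0, maternal_hr_bpm=90.0, seed=2)
        )
        noisy = with_noise_snr(session.get("chest", "ecg"), 10.0, seed=3)
        beats = detect_r_peaks(noisy)
        sens, ppv = match_events(beats.times_ms, truth.maternal_beat_ms)
        assert sens >= 0.98 and ppv >= 0.98


class TestHrFromBeats:
    def test_reported_maternal_interval(self):
        """A mean R-R of 635 ms displays as 94 bpm."""
        beats = BeatSeries(np.arange(20) * 635.0)
        hr = hr_from_beats(beats, window_ms=20_000.0)
        assert np.round(60000.0 / 635.0) == 94
        assert np.nanmean(hr.display_values()) == 94

    def test_one_second_intervals_give_60(self):
        beats = BeatSeries(np.arange(15) * 1000.0)
        hr = hr_from_beats(beats, window_ms=10_000.0)
        np.testing.assert_allclose(hr.values[np.isfinite(hr.values)], 60.0)

    def test_fetal_interval_unrounded(self):
        """344 ms intervals give 174.42 bpm unrounded (174 displayed)."""
        beats = BeatSeries(np.arange(40) * 344.0)
        hr = hr_from_beats(beats, window_ms=10_000.0, vital="fhr_bpm")
        finite = hr.values[np.isfinite(hr.values)]
        np.testing.assert_allclose(finite, 60000.0 / 344.0, rtol=1e-9)
        assert np.all(hr.display_values()[np.isfinite(hr.values)] == 174)

    def test_sparse_window_missing(self):
        beats = BeatSeries(np.array([0.0, 700.0, 30_000.0]))
        hr = hr_from_beats(beats, window_ms=5_000.0)
        assert np.isnan(hr.values).any()

    def test_matches_brute_force_oracle(self):
        """Windowed HR equals direct 60000/mean-interval recomputation."""
        rng = np.random.default_rng(7)
        times = np.cumsum(rng.uniform(600, 900, 120))
        beats = BeatSeries(times)
        window = 15_000.0
        hr = hr_from_beats(beats, window_ms=window)
        for c, v in zip(hr.times_ms, hr.values):
            w = times[(times >= c - window / 2) & (times <= c + window / 2)]
            expect = 60000.0 / np.mean(np.diff(w)) if w.size >= 2 else np.nan
            if np.isnan(expect):
                assert np.isnan(v)
            else:
                assert v == pytest.approx(expect, rel=1e-12)


class TestDetectPpgPulses:
    def test_pulse_rate_recovered(self):
        session, truth = simulate_session(
            ScenarioConfig(duration_s=60.0, maternal_hr_bpm=75.0, seed=4)
        )
        pulses = detect_ppg_pulses(session.get("limb", "ppg_ir"))
        assert abs(pulses.n - truth.pulse_time_ms.size) <= 1

    def test_flat_signal_empty(self):
        ppg = SensorStream("ppg_ir", "limb", 256.0, np.ones(256 * 10))
        assert detect_ppg_pulses(ppg).n == 0

    def test_pulse_times_track_true_delay(self):
        """Pulses land one PAT (250 ms) after the R peaks, within a sample."""
        session, truth = simulate_session(
            ScenarioConfig(duration_s=60.0, true_pat_ms=250.0, seed=5)
        )
        ppg = session.get("limb", "ppg_ir")
        pulses = detect_ppg_pulses(ppg)
        expected = truth.maternal_beat_ms + 250.0
        err = np.abs(pulses.times_ms[:, None] - expected[None, :]).min(axis=1)
        assert err.max() <= ppg.dt_ms + 1e-9


class TestComputeSpo2:
    def test_ratio_half_maps_to_97_5(self):
        session, truth = simulate_session(
            ScenarioConfig(duration_s=60.0, spo2_ratio_R=0.5, seed=6)
        )
        spo2 = compute_spo2(session.get("limb", "ppg_red"), session.get("limb", "ppg_ir"))
        assert np.nanmean(spo2.values) == pytest.approx(truth.spo2_pct(), abs=0.2)
        assert truth.spo2_pct() == 97.5

    def test_low_ratio_clamps_at_100(self):
        session, _ = simulate_session(
            ScenarioConfig(duration_s=60.0, spo2_ratio_R=0.35, seed=7)
        )
        spo2 = compute_spo2(session.get("limb", "ppg_red"), session.get("limb", "ppg_ir"))
        assert np.nanmax(spo2.values) <= 100.0
        assert np.nanmean(spo2.values) == pytest.approx(100.0, abs=0.3)

    def test_dead_red_channel_gives_missing(self):
        session, _ = simulate_session(ScenarioConfig(duration_s=30.0, seed=8))
        red = session.get("limb", "ppg_red")
        dead = SensorStream("ppg_red", "limb", red.rate_hz, np.zeros(red.n))
        with pytest.warns(UserWarning, match="no valid windows"):
            spo2 = compute_spo2(dead, session.get("limb", "ppg_ir"))
        assert np.all(np.isnan(spo2.values))

    def test_monotone_decreasing_in_ratio(self):
        values = []
        for i, ratio in enumerate((0.5, 0.8, 1.1, 1.4)):
            session, _ = simulate_session(
                ScenarioConfig(duration_s=40.0, spo2_ratio_R=ratio, seed=20 + i)
            )
            spo2 = compute_spo2(session.get("limb", "ppg_red"), session.get("limb", "ppg_ir"))
            values.append(np.nanmean(spo2.values))
        assert np.all(np.diff(values) < 0)


@pytest.fixture(scope="module")
def resp_session():
    return simulate_session(ScenarioConfig(duration_s=180.0, resp_hz=0.25, seed=9))


class TestRespiratoryRate:
    def test_quarter_hz_gives_15(self, resp_session):
        session, _ = resp_session
        from mfv.maternal import detect_r_peaks

        beats = detect_r_peaks(session.get("chest", "ecg"))
        rr = respiratory_rate(
            session.get("chest", "accel_x"),
            session.get("chest", "accel_y"),
            session.get("chest", "ecg"),
            beats,
        )
        assert np.nanmean(rr.values) == pytest.approx(15.0, abs=0.5)

    def test_consistent_sources_at_point_two_hz(self):
        session, _ = simulate_session(
            ScenarioConfig(duration_s=180.0, resp_hz=0.2, seed=10)
        )
        from mfv.maternal import detect_r_peaks

        beats = detect_r_peaks(session.get("chest", "ecg"))
        rr = respiratory_rate(
            session.get("chest", "accel_x"),
            session.get("chest", "accel_y"),
            session.get("chest", "ecg"),
            beats,
        )
        assert np.nanmean(rr.values) == pytest.approx(12.0, abs=0.5)

    def test_no_modulation_missing(self):
        session, _ = simulate_session(
            ScenarioConfig(duration_s=90.0, resp_accel_amp_g=0.0, edr_mod_depth=0.0, seed=11)
        )
        rr = respiratory_rate(
            session.get("chest", "accel_x"), session.get("chest", "accel_y")
        )
        # a perfectly flat band has no dominant peak passing the quality gate
        assert np.all(np.isnan(rr.values))

    def test_invariant_to_offset_and_gain(self, resp_session):
        session, _ = resp_session
        ax = session.get("chest", "accel_x")
        ay = session.get("chest", "accel_y")
        rr0 = respiratory_rate(ax, ay)
        scaled = SensorStream("accel_x", "chest", ax.rate_hz, 7.0 * ax.samples + 3.0)
        rr1 = respiratory_rate(scaled, ay)
        np.testing.assert_allclose(rr1.values, rr0.values, equal_nan=True)

    def test_short_window_rejected(self, resp_session):
        session, _ = resp_session
        with pytest.raises(ValidationError):
            respiratory_rate(
                session.get("chest", "accel_x"),
                session.get("chest", "accel_y"),
                window_ms=10_000.0,
            )


class TestTemperature:
    def test_constant_identity(self):
        temp = SensorStream("temp", "chest", 0.2, np.full(60, 36.8))
        out = temperature_series(temp)
        np.testing.assert_allclose(out.values, 36.8)

    def test_spike_removed_by_median(self):
        x = np.full(60, 36.8)
        x[30] = 43.0
        out = temperature_series(SensorStream("temp", "chest", 0.2, x))
        assert out.values[30] == pytest.approx(36.8)

    def test_linear_ramp_preserved(self):
        """36→38 degC over an hour survives smoothing within 0.05 degC."""
        session, _ = simulate_session(
            ScenarioConfig(duration_s=3600.0, temp_linear_ramp=(36.0, 38.0), seed=12)
        )
        temp = session.get("chest", "temp")
        out = temperature_series(temp)
        expected = 36.0 + 2.0 * temp.times_ms / (3600.0 * 1000.0)
        assert np.abs(out.values - expected).max() < 0.05
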