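"""Fetal heart rate, Doppler audio, uterine contractions, fetal ECG isolation."""

import numpy as np
import pytest

from mfv.abdominal import (
    ContractionEvent,
    EhgCalibration,
    detect_contractions,
    detect_fhr,
    doppler_envelope,
    export_doppler_audio,
    isolate_fetal_ecg,
)
from mfv.core import SensorStream, ValidationError
from mfv.io import read_wav
from mfv.maternal import detect_r_peaks
from mfv.simulate import ScenarioConfig, simulate_session, _piecewise

from conftest import match_events


class TestDopplerEnvelope:
    def test_silence_gives_zero(self):
        d = SensorStream("doppler", "abdominal", 504.0, np.zeros(504 * 10))
        env = doppler_envelope(d)
        np.testing.assert_allclose(env.samples, 0.0, atol=1e-12)

    def test_single_burst_single_lobe(self):
        x = np.zeros(504 * 10)
        t = np.arange(504 * 10) / 504.0
        sel = (t >= 5.0) & (t < 5.05)
        x[sel] = np.sin(2 * np.pi * 100.0 * t[sel])
        env = doppler_envelope(SensorStream("doppler", "abdominal", 504.0, x))
        peak = np.argmax(env.samples)
        assert abs(peak / 504.0 - 5.025) < 0.05
        # energy concentrated near the burst
        far = env.samples[np.abs(t - 5.025) > 0.5]
        assert far.max() < 0.05 * env.samples[peak]

    def test_s1_s2_peak_count_at_140bpm(self, quiet_session):
        """140 fetal bpm yields ~280 envelope peaks per minute (S1 + S2)."""
        _, session, truth = quiet_session
        env = doppler_envelope(session.get("abdominal", "doppler"))
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(
            env.samples, prominence=0.2 * env.samples.max(), distance=int(0.06 * 504)
        )
        per_min = peaks.size * 60.0 / (env.duration_ms / 1000.0)
        assert per_min == pytest.approx(280.0, abs=4.0)


class TestDetectFhr:
    def test_140_not_280(self, quiet_session):
        """S1/S2 pairing: the reported rate is 140, never the 280 peak rate."""
        _, session, truth = quiet_session
        env = doppler_envelope(session.get("abdominal", "doppler"))
        beats, fhr = detect_fhr(env)
        finite = fhr.values[np.isfinite(fhr.values)]
        assert finite.size > 0
        assert np.abs(finite - 140.0).max() <= 2.0
        assert beats.n == pytest.approx(truth.fetal_beat_ms.size, abs=2)

    def test_silence_missing(self):
        d = SensorStream("doppler", "abdominal", 504.0, np.zeros(504 * 20))
        env = doppler_envelope(d)
        _, fhr = detect_fhr(env)
        assert np.all(np.isnan(fhr.values))

    @pytest.mark.parametrize("gap_ms", [100.0, 150.0, 200.0])
    def test_never_double_counts(self, gap_ms):
        session, _ = simulate_session(
            ScenarioConfig(duration_s=45.0, fetal_hr_bpm=140.0, s1_s2_gap_ms=gap_ms, seed=13)
        )
        env = doppler_envelope(session.get("abdominal", "doppler"))
        _, fhr = detect_fhr(env)
        finite = fhr.values[np.isfinite(fhr.values)]
        assert not np.any(np.abs(finite - 280.0) < 20.0)
        assert np.median(np.abs(finite - 140.0)) <= 2.0

    def test_tracks_sweep(self):
        """FHR follows a 110→180 bpm ramp within 3 bpm."""
        profile = [(i * 10.0, 110.0 + 70.0 * i / 29.0) for i in range(30)]
        session, _ = simulate_session(
            ScenarioConfig(duration_s=300.0, fetal_hr_bpm=profile, seed=14)
        )
        env = doppler_envelope(session.get("abdominal", "doppler"))
        _, fhr = detect_fhr(env)
        expected = np.asarray(_piecewise(profile, fhr.times_ms / 1000.0))
        finite = np.isfinite(fhr.values)
        assert finite.mean() > 0.95
        assert np.abs(fhr.values[finite] - expected[finite]).max() <= 3.0


class TestDopplerAudio:
    def test_normalized_full_scale_at_504(self, quiet_session, tmp_path):
        _, session, _ = quiet_session
        path = tmp_path / "doppler.wav"
        export_doppler_audio(session.get("abdominal", "doppler"), path)
        rate, x = read_wav(path)
        assert rate == 504.0
        assert np.abs(x).max() == pytest.approx(1.0, abs=1e-4)

    def test_zero_signal_stays_zero(self, tmp_path):
        d = SensorStream("doppler", "abdominal", 504.0, np.zeros(504))
        path = tmp_path / "zero.wav"
        export_doppler_audio(d, path)
        _, x = read_wav(path)
        np.testing.assert_allclose(x, 0.0)

    def test_round_trip_matches_normalized_input(self, quiet_session, tmp_path):
        _, session, _ = quiet_session
        d = session.get("abdominal", "doppler")
        path = tmp_path / "doppler.wav"
        export_doppler_audio(d, path)
        _, x = read_wav(path)
        expected = d.samples / np.abs(d.samples).max()
        assert x.size == d.n
        assert np.abs(x - expected).max() < 1e-3  # 16-bit encoding precision

    def test_empty_rejected(self, tmp_path):
        d = SensorStream("doppler", "abdominal", 504.0, np.array([]))
        with pytest.raises(ValidationError):
            export_doppler_audio(d, tmp_path / "x.wav")


CONTRACTIONS = [(100.0, 60.0, 5.0), (280.0, 70.0, 6.0), (460.0, 60.0, 4.0)]


@pytest.fixture(scope="module")
def labor_session():
    return simulate_session(
        ScenarioConfig(
            duration_s=600.0,
            contraction_schedule=CONTRACTIONS,
            noise={"ehg": 0.2},
            seed=15,
        )
    )


class TestContractions:
    def test_three_bursts_three_events(self, labor_session):
        session, truth = labor_session
        events, _ = detect_contractions(
            session.get("abdominal", "ehg1"), session.get("abdominal", "ehg2")
        )
        assert len(events) == 3
        for ev, (onset_ms, _, _, _) in zip(events, truth.contraction_events):
            assert abs(ev.onset_ms - onset_ms) <= 15_000.0

    def test_flat_signal_no_events(self):
        flat = SensorStream("ehg1", "abdominal", 500.0, np.zeros(500 * 600))
        events, toco = detect_contractions(flat)
        assert events == []
        np.testing.assert_allclose(toco.samples, 0.0, atol=1e-12)

    def test_event_count_gain_invariant(self, labor_session):
        session, _ = labor_session
        e1 = session.get("abdominal", "ehg1")
        e2 = session.get("abdominal", "ehg2")
        base, _ = detect_contractions(e1, e2)
        scaled, _ = detect_contractions(
            SensorStream("ehg1", "abdominal", 500.0, 5.0 * e1.samples),
            SensorStream("ehg2", "abdominal", 500.0, 5.0 * e2.samples),
        )
        assert len(scaled) == len(base)

    def test_calibration_affine_map(self, labor_session):
        """gain 2, offset 5: a tocogram sample of 10 units reads 25 mmHg."""
        session, _ = labor_session
        calib = EhgCalibration(gain=2.0, offset=5.0)
        _, raw = detect_contractions(
            session.get("abdominal", "ehg1"), session.get("abdominal", "ehg2")
        )
        _, mmhg = detect_contractions(
            session.get("abdominal", "ehg1"),
            session.get("abdominal", "ehg2"),
            calib=calib,
        )
        np.testing.assert_allclose(mmhg.samples, 2.0 * raw.samples + 5.0, rtol=1e-9)
        assert mmhg.units == "mmHg"
        assert calib.apply(np.array([10.0]))[0] == 25.0

    def test_event_invariants(self, labor_session):
        session, _ = labor_session
        events, _ = detect_contractions(
            session.get("abdominal", "ehg1"), session.get("abdominal", "ehg2")
        )
        for ev in events:
            assert ev.onset_ms < ev.peak_ms < ev.offset_ms
            assert not ev.flagged  # durations inside the 30-300 s band

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValidationError):
            EhgCalibration(gain=0.0)

    def test_bad_event_geometry_rejected(self):
        with pytest.raises(ValidationError):
            ContractionEvent(onset_ms=10.0, peak_ms=5.0, offset_ms=20.0, amplitude=1.0)


class TestIsolateFetalEcg:
    def test_mixture_recall_and_residual(self, clinical_rates_session, clinical_rates_beats):
        """At a 0.1 fetal/maternal amplitude ratio the fetus is recovered."""
        _, session, truth = clinical_rates_session
        abd = session.get("abdominal", "ecg")
        residual, fetal = isolate_fetal_ecg(abd, clinical_rates_beats)
        sens, _ = match_events(fetal.times_ms, truth.fetal_beat_ms)
        assert sens >= 0.9
        idx = np.round(truth.maternal_beat_ms / abd.dt_ms).astype(int)
        idx = idx[(idx > 250) & (idx < abd.n - 250)]
        ratio = np.sqrt(
            np.mean(residual.samples[idx] ** 2) / np.mean(abd.samples[idx] ** 2)
        )
        assert ratio < 0.2

    def test_no_fetal_component_empty(self):
        session, _ = simulate_session(
            ScenarioConfig(duration_s=60.0, maternal_hr_bpm=94.0, fetal_amp_ratio=0.0, seed=16)
        )
        beats = detect_r_peaks(session.get("chest", "ecg"))
        with pytest.warns(UserWarning, match="no fetal"):
            _, fetal = isolate_fetal_ecg(session.get("abdominal", "ecg"), beats)
        assert fetal.n == 0

    def test_fetal_only_passthrough(self):
        """With no maternal projection the residual is the input signal."""
        session, truth = simulate_session(
            ScenarioConfig(
                duration_s=60.0,
                maternal_hr_bpm=94.0,
                fetal_hr_bpm=174.0,
                abd_maternal_amp=0.0,
                seed=17,
            )
        )
        abd = session.get("abdominal", "ecg")
        beats = detect_r_peaks(session.get("chest", "ecg"))
        residual, fetal = isolate_fetal_ecg(abd, beats)
        # the near-zero template removes almost nothing
        assert np.abs(residual.samples - abd.samples).max() < 0.2 * np.abs(abd.samples).max()
        err = np.abs(fetal.times_ms[:, None] - truth.fetal_beat_ms[None, :]).min(axis=1)
        assert np.median(err) <= abd.dt_ms + 1e-9

    def test_few_maternal_beats_rejected(self, clinical_rates_session):
        _, session, _ = clinical_rates_session
        from mfv.core import BeatSeries

        sparse = BeatSeries(np.arange(5) * 640.0 + 500.0)
        with pytest.raises(ValidationError, match="10 maternal beats"):
            isolate_fetal_ecg(session.get("abdominal", "ecg"), sparse)

    def test_residual_energy_strictly_reduced(self, clinical_rates_session, clinical_rates_beats):
        _, session, truth = clinical_rates_session
        abd = session.get("abdominal", "ecg")
        residual, _ = isolate_fetal_ecg(abd, clinical_rates_beats)
        idx = np.round(truth.maternal_beat_ms / abd.dt_ms).astype(int)
        idx = idx[(idx > 250) & (idx < abd.n - 250)]
        assert np.sum(residual.samples[idx] ** 2) < np.sum(abd.samples[idx] ** 2)
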