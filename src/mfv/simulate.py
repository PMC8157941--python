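"""Synthetic maternal-fetal monitoring sessions with full ground truth.

Generates every stream the pipeline consumes, at the device's native
rates, from a declarative scenario: chest ECG (Gaussian-sum PQRST template
train with respiratory amplitude modulation), chest accelerometry (gravity
baseline per scheduled posture plus a respiratory sinusoid), skin
temperature, dual-wavelength PPG (pulse waves delayed by the true pulse
arrival time, AC/DC chosen to realize the requested ratio-of-ratios),
abdominal Doppler (Hann-windowed S1/S2 tone-burst pairs per fetal beat)
and abdominal biopotentials (maternal ECG projection + fetal ECG at a
tenth of the amplitude + electrohysterography bursts per scheduled
contraction).

Morphology realism is deliberately limited — timing fidelity is what the
detection algorithms are tested on, so every emitted event time is exact
by construction and returned in :class:`GroundTruth`.  All randomness is
driven by the scenario seed; identical configs produce bit-identical
sessions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import SensorStream, SyncedSession, ValidationError
from .posture import CANONICAL_DIRECTIONS

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "simulate_session",
    "cold_pressor_scenario",
    "revert_cold_pressor",
    "with_noise_snr",
]

#: profile: either a constant or a piecewise-constant [(start_s, value), ...]
Profile = float | list


def _piecewise(profile: Profile, t_s: np.ndarray | float) -> np.ndarray | float:
    if isinstance(profile, (int, float)):
        return np.full_like(np.asarray(t_s, dtype=float), float(profile)) if np.ndim(t_s) else float(profile)
    starts = np.array([p[0] for p in profile], dtype=float)
    values = np.array([p[1] for p in profile], dtype=float)
    idx = np.clip(np.searchsorted(starts, t_s, side="right") - 1, 0, values.size - 1)
    return values[idx]


@dataclass
class ScenarioConfig:
    """Declarative scenario; every field has a ground-truth counterpart.

    Rate-like fields accept a constant or a piecewise-constant profile
    ``[(start_s, value), ...]``.  Noise levels are additive Gaussian SDs in
    each channel's physical units (all zero by default: the clean world the
    detection guarantees are stated for).
    """

    duration_s: float = 300.0
    maternal_hr_bpm: Profile = 80.0
    fetal_hr_bpm: Profile = 140.0
    fetal_amp_ratio: float = 0.1
    abd_maternal_amp: float = 0.5   # maternal ECG projection on the abdomen
    true_pat_ms: Profile = 250.0
    spo2_ratio_R: float = 0.5
    resp_hz: float = 0.25
    s1_s2_gap_ms: float = 150.0
    sbp_mmhg: Profile = 120.0
    dbp_mmhg: Profile = 80.0
    temp_c: Profile = 36.8
    temp_linear_ramp: tuple[float, float] | None = None  # (start value, end value)
    posture_schedule: list = field(default_factory=lambda: [(0.0, "supine")])
    contraction_schedule: list = field(default_factory=list)  # (onset_s, dur_s, amplitude)
    motion_schedule: list = field(default_factory=list)       # (start_s, dur_s, amp_g)
    resp_accel_amp_g: float = 0.01
    edr_mod_depth: float = 0.1
    ppg_perfusion: float = 0.02
    baseline_wander_amp: float = 0.0   # 0.05 Hz wander on ECG-like channels
    noise: dict = field(default_factory=dict)  # channel -> SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        events = sorted(self.contraction_schedule)
        for (o1, d1, _), (o2, _, _) in zip(events, events[1:]):
            if o1 + d1 > o2:
                raise ValidationError(
                    f"overlapping contractions at {o1:g}s and {o2:g}s"
                )
        for _, posture in self.posture_schedule:
            if posture not in CANONICAL_DIRECTIONS:
                raise ValidationError(f"unknown posture {posture!r}")


@dataclass
class GroundTruth:
    """Exact event times and derived-value targets implied by the scenario."""

    maternal_beat_ms: np.ndarray
    fetal_beat_ms: np.ndarray
    pulse_time_ms: np.ndarray
    pat_ms: np.ndarray               # per maternal beat
    breath_rate_brpm: float
    spo2_ratio_R: float
    contraction_events: list         # (onset_ms, peak_ms, offset_ms, amplitude)
    posture_labels: np.ndarray       # per 52 Hz accel sample
    sbp_at_beats: np.ndarray
    dbp_at_beats: np.ndarray
    hr_at_beats: np.ndarray

    def spo2_pct(self, c0: float = 110.0, c1: float = 25.0) -> float:
        return float(np.clip(c0 - c1 * self.spo2_ratio_R, 0.0, 100.0))


def _beat_times_s(rate_profile: Profile, duration_s: float, start_s: float = 0.5) -> np.ndarray:
    """Event times from an instantaneous-rate profile (bpm)."""
    times = []
    t = start_s
    while t < duration_s - 0.05:
        times.append(t)
        bpm = float(np.atleast_1d(_piecewise(rate_profile, t))[0])
        t += 60.0 / bpm
    return np.asarray(times)


# Gaussian-sum PQRST template: (amplitude, center s relative to R, width s)
_PQRST = (
    (0.12, -0.200, 0.025),
    (-0.10, -0.028, 0.010),
    (1.00, 0.000, 0.012),
    (-0.15, 0.028, 0.010),
    (0.30, 0.220, 0.060),
)


def _ecg_train(
    t: np.ndarray, beat_s: np.ndarray, amp: float = 1.0,
    width_scale: float = 1.0, mod: np.ndarray | None = None,
) -> np.ndarray:
    out = np.zeros_like(t)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    for k, b in enumerate(beat_s):
        m = 1.0 if mod is None else mod[k]
        lo = max(int((b - 0.45) / dt), 0)
        hi = min(int((b + 0.45) / dt) + 1, t.size)
        tt = t[lo:hi] - b
        seg = np.zeros_like(tt)
        for a, c, w in _PQRST:
            seg += a * np.exp(-0.5 * ((tt - c * width_scale) / (w * width_scale)) ** 2)
        out[lo:hi] += amp * m * seg
    return out


def _gauss_train(t: np.ndarray, centers_s: np.ndarray, amp, sigma_s: float) -> np.ndarray:
    out = np.zeros_like(t)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    amps = np.broadcast_to(np.asarray(amp, dtype=float), centers_s.shape)
    for b, a in zip(centers_s, amps):
        lo = max(int((b - 5 * sigma_s) / dt), 0)
        hi = min(int((b + 5 * sigma_s) / dt) + 1, t.size)
        out[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - b) / sigma_s) ** 2)
    return out


def _tone_burst(
    out: np.ndarray, t: np.ndarray, center_s: float, dur_s: float, freq_hz: float, amp: float
) -> None:
    """Add a Hann-windowed tone burst centered at ``center_s`` into ``out``."""
    dt = t[1] - t[0]
    lo = max(int((center_s - dur_s / 2) / dt), 0)
    hi = min(int((center_s + dur_s / 2) / dt) + 1, t.size)
    if hi <= lo:
        return
    win = np.hanning(hi - lo)
    out[lo:hi] += amp * win * np.sin(2 * np.pi * freq_hz * t[lo:hi])


def simulate_session(config: ScenarioConfig) -> tuple[SyncedSession, GroundTruth]:
    """Generate all device streams plus exact ground truth for a scenario."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dur = cfg.duration_s

    def grid(fs: float) -> np.ndarray:
        return np.arange(int(round(dur * fs))) / fs

    def noise_for(channel: str, n: int) -> np.ndarray:
        sd = float(cfg.noise.get(channel, 0.0))
        return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    # ---- event times -----------------------------------------------------
    m_beats = _beat_times_s(cfg.maternal_hr_bpm, dur)
    f_beats = _beat_times_s(cfg.fetal_hr_bpm, dur, start_s=0.4)
    pat_s = np.asarray(_piecewise(cfg.true_pat_ms, m_beats)) / 1000.0
    pulses = m_beats + pat_s

    # ---- chest ECG 512 Hz ------------------------------------------------
    t512 = grid(512.0)
    edr = 1.0 + cfg.edr_mod_depth * np.sin(2 * np.pi * cfg.resp_hz * m_beats)
    ecg = _ecg_train(t512, m_beats, amp=1.0, mod=edr)
    if cfg.baseline_wander_amp > 0:
        ecg += cfg.baseline_wander_amp * np.sin(2 * np.pi * 0.05 * t512)
    ecg += noise_for("ecg", t512.size)

    # ---- chest accel 52 Hz ----------------------------------------------
    t52 = grid(52.0)
    posture_labels = np.empty(t52.size, dtype=object)
    gravity = np.zeros((t52.size, 3))
    schedule = sorted(cfg.posture_schedule)
    starts = np.array([s for s, _ in schedule])
    idx = np.clip(np.searchsorted(starts, t52, side="right") - 1, 0, len(schedule) - 1)
    for k, (_, posture) in enumerate(schedule):
        sel = idx == k
        posture_labels[sel] = posture
        gravity[sel] = np.asarray(CANONICAL_DIRECTIONS[posture][0])
    resp_wave = cfg.resp_accel_amp_g * np.sin(2 * np.pi * cfg.resp_hz * t52)
    accel = gravity.copy()
    accel[:, 0] += resp_wave
    accel[:, 1] += 0.7 * resp_wave
    for start_s, dur_s, amp_g in cfg.motion_schedule:
        sel = (t52 >= start_s) & (t52 < start_s + dur_s)
        accel[sel] += rng.normal(0.0, amp_g, (int(sel.sum()), 3))
    for ax in range(3):
        accel[:, ax] += noise_for("accel", t52.size)

    # ---- temperature 0.2 Hz ---------------------------------------------
    t02 = grid(0.2)
    if cfg.temp_linear_ramp is not None:
        lo, hi = cfg.temp_linear_ramp
        temp = lo + (hi - lo) * t02 / dur
    else:
        temp = np.asarray(_piecewise(cfg.temp_c, t02), dtype=float)
    temp = temp + noise_for("temp", t02.size)

    # ---- limb PPG 256 Hz -------------------------------------------------
    t256 = grid(256.0)
    pulse_shape = _gauss_train(t256, pulses, 1.0, sigma_s=0.06)
    ac_ir = cfg.ppg_perfusion
    ac_red = cfg.spo2_ratio_R * cfg.ppg_perfusion
    ppg_ir = 1.0 + ac_ir * pulse_shape + noise_for("ppg", t256.size)
    ppg_red = 1.0 + ac_red * pulse_shape + noise_for("ppg", t256.size)

    # ---- abdominal Doppler 504 Hz ---------------------------------------
    t504 = grid(504.0)
    doppler = np.zeros_like(t504)
    gap_s = cfg.s1_s2_gap_ms / 1000.0
    for b in f_beats:
        _tone_burst(doppler, t504, b, 0.050, 100.0, 1.0)          # S1
        if b + gap_s < dur:
            _tone_burst(doppler, t504, b + gap_s, 0.030, 100.0, 0.6)  # S2
    doppler += noise_for("doppler", t504.size)

    # ---- abdominal biopotentials 500 Hz ----------------------------------
    t500 = grid(500.0)
    maternal_proj = _ecg_train(t500, m_beats, amp=cfg.abd_maternal_amp)
    # fetal amplitude is expressed relative to the nominal 0.5 maternal
    # projection so zeroing abd_maternal_amp leaves the fetus visible
    fetal_ecg = _ecg_train(t500, f_beats, amp=0.5 * cfg.fetal_amp_ratio, width_scale=0.5)
    ehg, contraction_truth = _ehg_bursts(t500, cfg, rng)
    abd_ecg = maternal_proj + fetal_ecg + noise_for("abd_ecg", t500.size)
    ehg1 = ehg + 0.3 * maternal_proj + 0.3 * fetal_ecg + noise_for("ehg", t500.size)
    ehg2 = 0.8 * ehg + 0.27 * maternal_proj + 0.27 * fetal_ecg + noise_for("ehg", t500.size)

    streams = [
        SensorStream("ecg", "chest", 512.0, ecg, units="mV"),
        SensorStream("accel_x", "chest", 52.0, accel[:, 0], units="g"),
        SensorStream("accel_y", "chest", 52.0, accel[:, 1], units="g"),
        SensorStream("accel_z", "chest", 52.0, accel[:, 2], units="g"),
        SensorStream("temp", "chest", 0.2, temp, units="degC"),
        SensorStream("ppg_red", "limb", 256.0, ppg_red, units="au"),
        SensorStream("ppg_ir", "limb", 256.0, ppg_ir, units="au"),
        SensorStream("doppler", "abdominal", 504.0, doppler, units="au"),
        SensorStream("ehg1", "abdominal", 500.0, ehg1, units="mV"),
        SensorStream("ehg2", "abdominal", 500.0, ehg2, units="mV"),
        SensorStream("ecg", "abdominal", 500.0, abd_ecg, units="mV"),
    ]
    session = SyncedSession(streams=streams)

    hr_at_beats = np.asarray(_piecewise(cfg.maternal_hr_bpm, m_beats), dtype=float)
    truth = GroundTruth(
        maternal_beat_ms=m_beats * 1000.0,
        fetal_beat_ms=f_beats * 1000.0,
        pulse_time_ms=pulses * 1000.0,
        pat_ms=pat_s * 1000.0,
        breath_rate_brpm=cfg.resp_hz * 60.0,
        spo2_ratio_R=cfg.spo2_ratio_R,
        contraction_events=contraction_truth,
        posture_labels=posture_labels,
        sbp_at_beats=np.asarray(_piecewise(cfg.sbp_mmhg, m_beats), dtype=float),
        dbp_at_beats=np.asarray(_piecewise(cfg.dbp_mmhg, m_beats), dtype=float),
        hr_at_beats=hr_at_beats,
    )
    return session, truth


def _ehg_bursts(t: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator):
    """Contraction bursts: band-limited noise under a Hann envelope."""
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 500.0
    ehg = np.zeros_like(t)
    truth = []
    if not cfg.contraction_schedule:
        return ehg, truth
    nyq = fs / 2.0
    sos = sps.butter(4, [0.34 / nyq, 1.0 / nyq], btype="band", output="sos")
    for onset_s, dur_s, amp in sorted(cfg.contraction_schedule):
        sel = (t >= onset_s) & (t < onset_s + dur_s)
        n = int(sel.sum())
        if n == 0:
            continue
        burst = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n + int(4 * fs)))[: n]
        rms = np.sqrt(np.mean(burst**2))
        if rms > 0:
            burst = burst / rms
        ehg[sel] += amp * np.hanning(n) * burst
        truth.append(
            (
                onset_s * 1000.0,
                (onset_s + dur_s / 2.0) * 1000.0,
                (onset_s + dur_s) * 1000.0,
                float(amp),
            )
        )
    return ehg, truth


_COLD_PRESSOR_EPOCH_S = 120.0


def cold_pressor_scenario(baseline: ScenarioConfig) -> ScenarioConfig:
    """Insert a cold-pressor epoch mid-session.

    For 120 s centered in the session: pulse arrival time drops 15%, heart
    rate rises 10 bpm, and ground-truth systolic pressure rises 20 mmHg —
    the expected pressor response used to exercise the inverse PAT-BP
    relationship end to end.
    """
    for name in ("true_pat_ms", "maternal_hr_bpm", "sbp_mmhg"):
        if not isinstance(getattr(baseline, name), (int, float)):
            raise ValidationError(f"cold pressor needs a constant baseline {name}")
    e0 = baseline.duration_s / 2.0 - _COLD_PRESSOR_EPOCH_S / 2.0
    e1 = e0 + _COLD_PRESSOR_EPOCH_S
    pat0 = float(baseline.true_pat_ms)
    hr0 = float(baseline.maternal_hr_bpm)
    sbp0 = float(baseline.sbp_mmhg)
    return replace(
        copy.deepcopy(baseline),
        true_pat_ms=[(0.0, pat0), (e0, 0.85 * pat0), (e1, pat0)],
        maternal_hr_bpm=[(0.0, hr0), (e0, hr0 + 10.0), (e1, hr0)],
        sbp_mmhg=[(0.0, sbp0), (e0, sbp0 + 20.0), (e1, sbp0)],
    )


def revert_cold_pressor(config: ScenarioConfig) -> ScenarioConfig:
    """Inverse of :func:`cold_pressor_scenario` (restores the constants)."""
    out = copy.deepcopy(config)
    for name in ("true_pat_ms", "maternal_hr_bpm", "sbp_mmhg"):
        profile = getattr(out, name)
        if isinstance(profile, list):
            setattr(out, name, float(profile[0][1]))
    return out


def with_noise_snr(stream: SensorStream, snr_db: float, seed: int = 0) -> SensorStream:
    """Add white Gaussian noise at a given SNR relative to the signal RMS."""
    rng = np.random.default_rng(seed)
    x = stream.samples
    rms = np.sqrt(np.mean(x**2))
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    return replace(stream, samples=x + rng.normal(0.0, sigma, x.size))
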