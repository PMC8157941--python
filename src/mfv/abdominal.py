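"""Abdominal-sensor analytics: Doppler fetal heart rate, electrohysterography
(EHG) uterine-contraction detection, Doppler audio export, and fetal ECG
isolation by maternal-template cancellation.

Each fetal cardiac cycle produces two Doppler-audible valve-closure sounds:
S1 (tricuspid/mitral closure) and S2 (pulmonary semilunar closure).  The
fetal heart rate estimator must therefore pair the two peaks per beat —
counting S1 and S2 separately would double the rate.  Pairing uses a
greedy nearest-neighbor rule with an S1→S2 gap prior of 80-250 ms, and the
beat period itself is confirmed by windowed autocorrelation of the envelope
(cardiotocography convention: 3.75 s window stepped by 0.25 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import io as _io
from .core import BeatSeries, SensorStream, ValidationError, VitalSeries
from .maternal import PanTompkinsConfig, detect_r_peaks

__all__ = [
    "FetalBeatSeries",
    "ContractionEvent",
    "EhgCalibration",
    "doppler_envelope",
    "detect_fhr",
    "export_doppler_audio",
    "detect_contractions",
    "isolate_fetal_ecg",
]

S1_S2_GAP_MS = (80.0, 250.0)
FHR_PERIOD_MS = (250.0, 1000.0)  # 60-240 bpm


@dataclass
class FetalBeatSeries:
    """Fetal beats: one event per S1-S2 pair, plus the component peaks."""

    times_ms: np.ndarray
    s1_times_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    s2_times_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.s1_times_ms = np.asarray(self.s1_times_ms, dtype=float)
        self.s2_times_ms = np.asarray(self.s2_times_ms, dtype=float)
        if self.quality is None:
            self.quality = np.ones(self.times_ms.size, dtype=bool)

    @property
    def n(self) -> int:
        return int(self.times_ms.size)


@dataclass
class ContractionEvent:
    """One uterine contraction: onset, envelope peak, offset, amplitude."""

    onset_ms: float
    peak_ms: float
    offset_ms: float
    amplitude: float
    units: str = "au"
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_ms < self.peak_ms < self.offset_ms):
            raise ValidationError("contraction requires onset < peak < offset")
        duration_s = (self.offset_ms - self.onset_ms) / 1000.0
        if not (30.0 <= duration_s <= 300.0):
            self.flagged = True

    @property
    def duration_s(self) -> float:
        return (self.offset_ms - self.onset_ms) / 1000.0


@dataclass
class EhgCalibration:
    """Affine envelope→pressure map: mmHg = gain * envelope + offset."""

    gain: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValidationError("calibration gain must be positive")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(x, dtype=float) + self.offset


def doppler_envelope(doppler: SensorStream, cutoff_hz: float = 25.0) -> SensorStream:
    """Rectified, low-pass (<30 Hz) envelope of the Doppler signal.

    If the input already looks enveloped (negligible energy above the
    audio band), rectification is still harmless, so no auto-detection
    branching is needed here; callers with pre-enveloped data can pass it
    straight through.
    """
    if doppler.duration_ms < 5000:
        raise ValidationError("Doppler envelope needs at least 5 s of signal")
    x = np.abs(np.nan_to_num(doppler.samples, nan=0.0))
    nyq = doppler.rate_hz / 2.0
    sos = sps.butter(4, min(cutoff_hz, 0.99 * nyq) / nyq, btype="low", output="sos")
    env = sps.sosfiltfilt(sos, x)
    env = np.maximum(env, 0.0)
    return SensorStream(
        label="doppler_env",
        sensor=doppler.sensor,
        rate_hz=doppler.rate_hz,
        samples=env,
        t0_ms=doppler.t0_ms,
        units=doppler.units,
    )


def _autocorr_period_ms(env: np.ndarray, fs: float, confidence: float):
    """Beat period from envelope autocorrelation.

    Among local maxima within 85% of the strongest peak in the physiological
    period range, the smallest lag is chosen: the full beat period always
    aligns both the S1 and S2 trains with themselves, so the true period is
    the shortest lag of near-maximal correlation, while the S2→S1 partial
    alignment stays well below it.  Returns (period_ms, confidence) or None.
    """
    x = env - env.mean()
    if np.ptp(x) == 0:
        return None
    ac = sps.correlate(x, x, mode="full")[x.size - 1 :]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lo = int(round(FHR_PERIOD_MS[0] / 1000.0 * fs))
    hi = min(int(round(FHR_PERIOD_MS[1] / 1000.0 * fs)), ac.size - 1)
    if hi <= lo:
        return None
    seg = ac[lo : hi + 1]
    peaks, _ = sps.find_peaks(seg)
    if peaks.size == 0:
        return None
    best = float(seg[peaks].max())
    if best < confidence:
        return None
    near = peaks[seg[peaks] >= 0.85 * best]
    lag = lo + int(near.min())
    return 1000.0 * lag / fs, best


def detect_fhr(
    envelope: SensorStream,
    window_ms: float = 3750.0,
    step_ms: float = 250.0,
    confidence: float = 0.45,
) -> tuple[FetalBeatSeries, VitalSeries]:
    """Fetal heart rate and paired S1/S2 beats from a Doppler envelope.

    Per window the envelope autocorrelation gives the beat period (windows
    whose best correlation falls below ``confidence`` report a missing
    rate).  Envelope peaks are then paired S1→S2 with the gap prior so each
    fetal heartbeat is counted once; FHR = 60000 / mean beat period.
    """
    fs = envelope.rate_hz
    x = envelope.samples
    n_win = int(round(window_ms / 1000.0 * fs))
    n_step = max(int(round(step_ms / 1000.0 * fs)), 1)
    centers, rates = [], []
    for start in range(0, max(x.size - n_win + 1, 1), n_step):
        seg = x[start : start + n_win]
        if seg.size < n_win // 2:
            break
        res = _autocorr_period_ms(seg, fs, confidence)
        centers.append(envelope.t0_ms + (start + seg.size / 2.0) * envelope.dt_ms)
        rates.append(60000.0 / res[0] if res is not None else np.nan)
    fhr = VitalSeries(np.array(centers), np.array(rates), "fhr_bpm", window_ms)

    beats = _pair_s1_s2(envelope, fhr)
    return beats, fhr


def _pair_s1_s2(envelope: SensorStream, fhr: VitalSeries) -> FetalBeatSeries:
    x = envelope.samples
    fs = envelope.rate_hz
    if np.ptp(x) == 0:
        return FetalBeatSeries(np.array([]))
    min_dist = max(int(round(0.9 * S1_S2_GAP_MS[0] / 1000.0 * fs)), 1)
    prom = 0.25 * float(np.percentile(x, 95))
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=prom)
    if peaks.size == 0:
        return FetalBeatSeries(np.array([]))
    pt = envelope.t0_ms + peaks * envelope.dt_ms

    # expected beat period at each peak, from the windowed FHR track
    finite = np.isfinite(fhr.values)
    if finite.any():
        period_at = np.interp(pt, fhr.times_ms[finite], 60000.0 / fhr.values[finite])
    else:
        period_at = np.full(pt.size, np.nan)

    s1, s2, beat_q = [], [], []
    i = 0
    while i < pt.size:
        gap = pt[i + 1] - pt[i] if i + 1 < pt.size else np.inf
        if S1_S2_GAP_MS[0] <= gap <= S1_S2_GAP_MS[1]:
            # candidate pair; reject if the gap looks like a full beat period
            per = period_at[i]
            if np.isfinite(per) and abs(gap - per) < abs(gap - np.clip(per - gap, *S1_S2_GAP_MS)):
                s1.append(pt[i])
                s2.append(np.nan)
                beat_q.append(False)
                i += 1
                continue
            s1.append(pt[i])
            s2.append(pt[i + 1])
            beat_q.append(True)
            i += 2
        else:
            s1.append(pt[i])
            s2.append(np.nan)
            beat_q.append(False)
            i += 1
    s1a = np.array(s1)
    s2a = np.array(s2)
    qa = np.array(beat_q, dtype=bool)
    return FetalBeatSeries(times_ms=s1a, s1_times_ms=s1a, s2_times_ms=s2a, quality=qa)


def export_doppler_audio(doppler: SensorStream, path) -> None:
    """Export the Doppler stream as audio, normalized to [-1, 1].

    The file keeps the native 504 Hz sampling rate so playback reproduces
    the audible fetal Doppler of a bedside monitor.  All-zero input is
    written unscaled.
    """
    if doppler.n == 0:
        raise ValidationError("cannot export an empty Doppler stream")
    x = np.nan_to_num(doppler.samples, nan=0.0)
    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x / peak
    _io.export_wav(path, x, doppler.rate_hz)


def detect_contractions(
    ehg_ch1: SensorStream,
    ehg_ch2: SensorStream | None = None,
    calib: EhgCalibration | None = None,
    band_hz: tuple[float, float] = (0.34, 1.0),
    rms_window_s: float = 60.0,
    min_duration_s: float = 30.0,
    threshold_factor: float = 4.0,
) -> tuple[list[ContractionEvent], SensorStream]:
    """Uterine contractions from one or two EHG channels.

    Per channel: band-pass to the established electrohysterography band
    (0.34-1.0 Hz), then a moving RMS envelope (60 s window).  Channels are
    fused by pointwise maximum.  A baseline-adaptive threshold (median +
    ``threshold_factor`` x median absolute deviation) segments candidate
    events; onset/offset are refined to the half-prominence crossings so
    the 60 s RMS smear does not bias the onset.  Returns the events and the
    fused envelope as a tocogram, in mmHg when a calibration is given.
    """
    envs = []
    for ch in (ehg_ch1, ehg_ch2):
        if ch is None:
            continue
        envs.append(_ehg_envelope(ch, band_hz, rms_window_s))
    n = min(e.size for e in envs)
    fused = np.max(np.vstack([e[:n] for e in envs]), axis=0)
    fs_env = _ENV_RATE_HZ
    toco_units = "au"
    toco = fused
    if calib is not None:
        toco = calib.apply(fused)
        toco_units = "mmHg"
    tocogram = SensorStream(
        label="tocogram",
        sensor="abdominal",
        rate_hz=fs_env,
        samples=toco,
        t0_ms=ehg_ch1.t0_ms,
        units=toco_units,
    )

    baseline = float(np.median(fused))
    mad = float(np.median(np.abs(fused - baseline)))
    thr = baseline + threshold_factor * max(mad, 1e-12 * max(abs(baseline), 1.0))
    above = fused > thr
    if not above.any() or np.ptp(fused) == 0:
        return [], tocogram

    events: list[ContractionEvent] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[above[edges + 1]] + 1) if above.size else []
    stops = list(edges[~above[edges + 1]] + 1) if above.size else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [above.size]
    for i0, i1 in zip(starts, stops):
        peak_i = i0 + int(np.argmax(fused[i0:i1]))
        peak_v = fused[peak_i]
        half = baseline + 0.5 * (peak_v - baseline)
        # refine onset/offset to the half-prominence crossings
        on = peak_i
        while on > 0 and fused[on - 1] >= half:
            on -= 1
        off = peak_i
        while off < fused.size - 1 and fused[off + 1] >= half:
            off += 1
        if (off - on) / fs_env < min_duration_s:
            continue
        amp = peak_v - baseline
        if calib is not None:
            amp = calib.gain * amp  # amplitude above baseline scales by gain only
        events.append(
            ContractionEvent(
                onset_ms=ehg_ch1.t0_ms + on / fs_env * 1000.0,
                peak_ms=ehg_ch1.t0_ms + peak_i / fs_env * 1000.0,
                offset_ms=ehg_ch1.t0_ms + off / fs_env * 1000.0,
                amplitude=float(amp),
                units=toco_units,
            )
        )
    # merge events whose half-height supports overlap (same burst split by noise)
    merged: list[ContractionEvent] = []
    for ev in events:
        if merged and ev.onset_ms <= merged[-1].offset_ms:
            prev = merged.pop()
            top = prev if prev.amplitude >= ev.amplitude else ev
            merged.append(
                ContractionEvent(
                    onset_ms=prev.onset_ms,
                    peak_ms=top.peak_ms,
                    offset_ms=max(prev.offset_ms, ev.offset_ms),
                    amplitude=top.amplitude,
                    units=top.units,
                )
            )
        else:
            merged.append(ev)
    return merged, tocogram


_ENV_RATE_HZ = 20.0  # EHG envelope rate after decimation


def _ehg_envelope(ch: SensorStream, band_hz, rms_window_s: float) -> np.ndarray:
    """Band-pass + moving-RMS envelope, computed at 20 Hz.

    The EHG band sits far below the 500 Hz native rate, so the channel is
    decimated first; filtering at the native rate would push the Butterworth
    corner to ~1e-3 of Nyquist and become numerically fragile.
    """
    x = np.nan_to_num(ch.samples, nan=0.0)
    factor = max(int(round(ch.rate_hz / _ENV_RATE_HZ)), 1)
    if factor > 1:
        x = sps.decimate(x, factor, ftype="fir", zero_phase=True)
    fs = ch.rate_hz / factor
    nyq = fs / 2.0
    sos = sps.butter(4, [band_hz[0] / nyq, min(band_hz[1], 0.99 * nyq) / nyq],
                     btype="band", output="sos")
    filt = sps.sosfiltfilt(sos, x)
    n_rms = max(int(round(rms_window_s * fs)), 1)
    kernel = np.ones(n_rms) / n_rms
    return np.sqrt(np.convolve(filt**2, kernel, mode="same"))


def isolate_fetal_ecg(
    abd_ecg: SensorStream,
    maternal_beats: BeatSeries,
    template_halfwidth_ms: float = 300.0,
    fetal_config: PanTompkinsConfig | None = None,
) -> tuple[SensorStream, BeatSeries]:
    """Cancel the maternal ECG from the abdominal channel and detect fetal beats.

    The maternal QRS template is the median beat (±300 ms) across all
    chest-detected R times projected onto the abdominal channel; at each
    beat the template is subtracted with a per-beat least-squares scale.
    Fetal R peaks — typically an order of magnitude smaller than the
    maternal projection — are then detected on the residual with the QRS
    chain retuned to fetal rates (roughly 100-240 bpm).
    """
    x = np.nan_to_num(abd_ecg.samples, nan=0.0).copy()
    fs = abd_ecg.rate_hz
    # The template spans 60% of the median R-R on each side so slow
    # maternal repolarization tails are inside it, but each subtraction is
    # applied only within the beat's own cell (midpoint-to-midpoint of the
    # neighboring beats), so the cells tile the record: full coverage of
    # the maternal cycle with no double subtraction.
    half_ms = template_halfwidth_ms
    if maternal_beats.n > 2:
        med_rr = float(np.median(np.diff(maternal_beats.times_ms)))
        half_ms = float(np.clip(0.6 * med_rr, template_halfwidth_ms, 500.0))
    half = int(round(half_ms / 1000.0 * fs))
    all_idx = np.round((maternal_beats.times_ms - abd_ecg.t0_ms) / abd_ecg.dt_ms).astype(int)
    all_idx = all_idx[(all_idx >= 0) & (all_idx < x.size)]
    beat_idx = all_idx[(all_idx >= half) & (all_idx < x.size - half)]

    if maternal_beats.n > 0:
        if beat_idx.size < 10:
            raise ValidationError(
                f"need at least 10 maternal beats inside the record, got {beat_idx.size}"
            )
        segs = np.stack([x[i - half : i + half + 1] for i in beat_idx])
        template = np.median(segs, axis=0)
        dtemplate = np.gradient(template)
        residual = x.copy()
        if float(np.dot(template, template)) > 0:
            # cell boundaries: midpoints between consecutive beats.  The
            # outer cells stop at half an R-R interval: beyond that the
            # template holds the *neighbor* beat's repolarization, which
            # the record's edge beats do not have.
            mids = (all_idx[:-1] + all_idx[1:]) // 2
            half_rr = int(np.median(np.diff(all_idx)) // 2) if all_idx.size > 1 else half
            # the first cell reaches back only past its own P wave: farther
            # left the template holds the previous beat's T tail, which the
            # record's first beat does not have
            head = min(half_rr, int(round(0.25 * fs)))
            cell_lo = np.concatenate([[max(all_idx[0] - head, 0)], mids])
            cell_hi = np.concatenate([mids, [min(all_idx[-1] + half_rr + 1, x.size)]])
            max_lag = max(int(round(0.004 * fs)), 1)
            pad = np.pad(template, max_lag, mode="edge")
            dpad = np.pad(dtemplate, max_lag, mode="edge")
            for i, lo, hi in zip(all_idx, cell_lo, cell_hi):
                # template sample range overlapping this cell
                t_lo = max(lo - (i - half), 0)
                t_hi = min(hi - (i - half), template.size)
                if t_hi - t_lo < 3:
                    continue
                s_lo = i - half + t_lo
                s_hi = i - half + t_hi
                seg = residual[s_lo:s_hi]
                # integer-lag realignment of the *template* (chest beat
                # times land between abdominal samples); the cell itself
                # stays fixed so the tiling remains gap-free
                best_lag, best_dot = 0, -1.0
                for lag in range(-max_lag, max_lag + 1):
                    tmpl = pad[max_lag + t_lo - lag : max_lag + t_hi - lag]
                    dot = abs(float(np.dot(seg, tmpl)))
                    if dot > best_dot:
                        best_lag, best_dot = lag, dot
                tmpl = pad[max_lag + t_lo - best_lag : max_lag + t_hi - best_lag]
                dt_ = dpad[max_lag + t_lo - best_lag : max_lag + t_hi - best_lag]
                # LS fit on the template and its derivative (first-order
                # Taylor term absorbs the fractional-sample shift)
                basis = np.column_stack([tmpl, dt_])
                coef, *_ = np.linalg.lstsq(basis, seg, rcond=None)
                residual[s_lo:s_hi] = seg - basis @ coef
    else:
        residual = x.copy()

    res_stream = SensorStream(
        label="fetal_residual",
        sensor="abdominal",
        rate_hz=fs,
        samples=residual,
        t0_ms=abd_ecg.t0_ms,
        units=abd_ecg.units,
    )

    cfg = fetal_config or PanTompkinsConfig(
        band_hz=(12.0, 45.0),  # fetal QRS is ~half the maternal width

        integration_ms=80.0,
        refractory_ms=150.0,
        min_rr_ms=250.0,
        max_rr_ms=600.0,
        peak_window_ms=80.0,
    )
    try:
        fetal = detect_r_peaks(res_stream, cfg, kind="fetal_r_peak")
    except ValidationError:
        fetal = BeatSeries(np.array([]), kind="fetal_r_peak")

    # Amplitude gate: a fetal R wave is ~10% of the maternal projection;
    # anything below 3% is cancellation ripple, not a fetus.
    if fetal.n > 0 and beat_idx.size > 0:
        maternal_amp = float(np.median(np.abs(x[beat_idx])))
        floor = 0.03 * maternal_amp
        f_idx = np.round((fetal.times_ms - abd_ecg.t0_ms) / abd_ecg.dt_ms).astype(int)
        f_idx = np.clip(f_idx, 0, residual.size - 1)
        keep = np.abs(residual[f_idx]) >= floor
        fetal = BeatSeries(fetal.times_ms[keep], kind="fetal_r_peak",
                           quality=fetal.quality[keep])
    if fetal.n == 0:
        warnings.warn("no fetal R peaks found on the residual")
    return res_stream, fetal
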