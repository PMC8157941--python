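"""Maternal vital signs from chest and limb streams.

Heart rate comes from QRS detection on the chest ECG with a Pan-Tompkins
style detector (band-pass, differentiate, square, moving-window integrate,
adaptive dual thresholds with refractory period and search-back).  SpO2
uses the dual-wavelength ratio-of-ratios on the limb PPG.  Respiratory rate
fuses chest-wall motion from the x/y accelerometer axes with ECG-derived
respiration (beat amplitude modulation).  Temperature is a moving-median
smoothed direct reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import BeatSeries, SensorStream, ValidationError, VitalSeries

__all__ = [
    "PanTompkinsConfig",
    "detect_r_peaks",
    "hr_from_beats",
    "detect_ppg_pulses",
    "compute_spo2",
    "respiratory_rate",
    "temperature_series",
]


@dataclass
class PanTompkinsConfig:
    """Every constant of the QRS detection chain, exposed for tuning.

    Defaults are the classic adult values; the fetal detector reuses the
    same chain with a tighter refractory period and wider band (see
    :mod:`mfv.abdominal`).
    """

    band_hz: tuple[float, float] = (5.0, 15.0)
    integration_ms: float = 150.0
    refractory_ms: float = 200.0
    min_rr_ms: float = 250.0
    max_rr_ms: float = 2000.0
    search_back: bool = True
    threshold_factor: float = 0.25   # fraction of running peak level
    snr_suspect_db: float = 6.0      # local SNR below this -> suspect flag
    peak_window_ms: float = 150.0    # raw-signal refinement half-window


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(
    ecg: SensorStream, config: PanTompkinsConfig | None = None, kind: str = "r_peak"
) -> BeatSeries:
    """Detect QRS complexes on an ECG stream.

    Returns one event per QRS with millisecond times on the session clock.
    Events whose local signal-to-noise ratio is poor, or whose R-R interval
    falls outside the physiological band, are flagged suspect.  An
    all-constant stream yields an empty series with a warning.
    """
    cfg = config or PanTompkinsConfig()
    fs = ecg.rate_hz
    if ecg.duration_ms < 5000:
        raise ValidationError("QRS detection needs at least 5 s of signal")
    x = np.nan_to_num(ecg.samples, nan=0.0)
    if np.ptp(x) == 0:
        warnings.warn("constant ECG signal: no beats detected")
        return BeatSeries(np.array([]), kind=kind)

    # Pan-Tompkins chain: band-pass, 5-point derivative, squaring, MWI.
    # The signal is mirror-padded by 1 s so filter start-up transients do
    # not distort the first and last beats, then the pad is dropped.
    pad = int(round(fs))
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    bp = _bandpass(xp, fs, *cfg.band_hz)[pad : pad + x.size]
    deriv = np.gradient(bp)
    sq = deriv**2
    mwi = _moving_average(sq, int(round(cfg.integration_ms / 1000.0 * fs)))

    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    if peaks.size == 0:
        return BeatSeries(np.array([]), kind=kind)

    # Adaptive dual thresholds (signal / noise running estimates).
    spk = float(np.percentile(mwi[peaks], 75))
    npk = float(np.percentile(mwi, 50))
    accepted: list[int] = []
    missed_limit = int(round(cfg.max_rr_ms / 1000.0 * fs))
    candidates: list[int] = []
    for p in peaks:
        thr = npk + cfg.threshold_factor * (spk - npk)
        if mwi[p] >= thr:
            if accepted and p - accepted[-1] < refractory:
                if mwi[p] > mwi[accepted[-1]]:
                    accepted[-1] = p
                continue
            accepted.append(p)
            spk = 0.125 * mwi[p] + 0.875 * spk
        else:
            candidates.append(p)
            npk = 0.125 * mwi[p] + 0.875 * npk
        # search-back: if the expected beat window elapsed, take the best
        # sub-threshold candidate at half threshold
        if (
            cfg.search_back
            and accepted
            and candidates
            and p - accepted[-1] > missed_limit
        ):
            half = npk + 0.5 * cfg.threshold_factor * (spk - npk)
            window = [c for c in candidates if c > accepted[-1] + refractory]
            if window:
                best = max(window, key=lambda c: mwi[c])
                if mwi[best] >= half:
                    accepted.append(best)
                    accepted.sort()
                    spk = 0.25 * mwi[best] + 0.75 * spk
            candidates = []

    if not accepted:
        return BeatSeries(np.array([]), kind=kind)

    # Refine each detection to the raw-signal R-wave apex (MWI is delayed
    # by roughly half the integration window).
    half_w = int(round(cfg.peak_window_ms / 1000.0 * fs))
    refined = []
    for p in accepted:
        lo = max(p - half_w, 0)
        hi = min(p + half_w + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined_arr = np.unique(refined)

    # refinement collisions inside the refractory period: keep the
    # stronger band-passed peak (a weak candidate refined onto its window
    # edge must not shadow the true R wave)
    kept: list[int] = []
    for p in refined_arr:
        if kept and p - kept[-1] < refractory:
            if np.abs(bp[p]) > np.abs(bp[kept[-1]]):
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    idx = np.asarray(kept)

    times = ecg.t0_ms + idx * ecg.dt_ms
    quality = np.ones(times.size, dtype=bool)
    if times.size > 1:
        rr = np.diff(times)
        bad_rr = (rr < cfg.min_rr_ms) | (rr > cfg.max_rr_ms)
        quality[1:] &= ~bad_rr
    # local SNR flag: QRS peak energy vs surrounding median absolute level
    noise_level = np.median(np.abs(bp)) + 1e-12
    for i, p in enumerate(idx):
        snr_db = 20.0 * np.log10(np.abs(bp[p]) / noise_level + 1e-12)
        if snr_db < cfg.snr_suspect_db:
            quality[i] = False
    return BeatSeries(times, kind=kind, quality=quality)


def hr_from_beats(
    beats: BeatSeries, window_ms: float = 10_000.0, step_ms: float | None = None,
    vital: str = "hr_bpm",
) -> VitalSeries:
    """Heart rate as 60000 / mean(R-R interval) per sliding window.

    Windows with fewer than two good beats yield a missing value.  Values
    are unrounded; nearest-integer display rounding is applied by
    :meth:`mfv.core.VitalSeries.display_values`.
    """
    step = step_ms if step_ms is not None else window_ms / 2.0
    t = beats.good_times()
    if t.size == 0:
        return VitalSeries(np.array([]), np.array([]), vital, window_ms)
    start, stop = t[0], t[-1]
    centers = np.arange(start + window_ms / 2.0, max(stop - window_ms / 2.0, start) + step, step)
    if centers.size == 0:
        centers = np.array([(start + stop) / 2.0])
    values = np.full(centers.size, np.nan)
    for i, c in enumerate(centers):
        w = t[(t >= c - window_ms / 2.0) & (t <= c + window_ms / 2.0)]
        if w.size >= 2:
            values[i] = 60000.0 / np.mean(np.diff(w))
    return VitalSeries(centers, values, vital, window_ms)


def detect_ppg_pulses(
    ppg: SensorStream, fiducial: str = "peak", min_pulse_interval_ms: float = 250.0
) -> BeatSeries:
    """Detect one event per cardiac pulse on a PPG channel.

    The default fiducial is the pulse peak; ``fiducial="foot"`` instead
    returns the preceding waveform minimum (onset), which is less sensitive
    to reflected-wave morphology when measuring pulse arrival time.
    """
    fs = ppg.rate_hz
    if ppg.duration_ms < 5000:
        raise ValidationError("pulse detection needs at least 5 s of signal")
    x = np.nan_to_num(ppg.samples, nan=0.0)
    if np.ptp(x) == 0:
        return BeatSeries(np.array([]), kind="ppg_pulse")
    ac = _bandpass(x, fs, 0.5, 8.0)
    dist = max(int(round(min_pulse_interval_ms / 1000.0 * fs)), 1)
    prominence = 0.3 * float(np.percentile(np.abs(ac), 90))
    peaks, _ = sps.find_peaks(ac, distance=dist, prominence=prominence)
    if peaks.size == 0:
        return BeatSeries(np.array([]), kind="ppg_pulse")
    if fiducial == "foot":
        feet = []
        for p in peaks:
            lo = max(p - dist, 0)
            feet.append(lo + int(np.argmin(ac[lo : p + 1])))
        peaks = np.unique(feet)
    times = ppg.t0_ms + peaks * ppg.dt_ms
    return BeatSeries(times, kind="ppg_pulse")


def compute_spo2(
    red: SensorStream,
    ir: SensorStream,
    window_ms: float = 10_000.0,
    c0: float = 110.0,
    c1: float = 25.0,
) -> VitalSeries:
    """SpO2 from the red/infrared ratio-of-ratios.

    Per window: ``R = (AC_red / DC_red) / (AC_ir / DC_ir)`` with AC from
    detected pulse peak-to-trough amplitudes and DC the window mean;
    ``SpO2 = clamp(c0 - c1 * R, 0, 100)``.  The linear coefficients are an
    empirical calibration curve and must be overridable because each
    oximeter front end has its own.
    """
    t_lo = max(red.t0_ms, ir.t0_ms)
    t_hi = min(red.times_ms[-1] if red.n else red.t0_ms, ir.times_ms[-1] if ir.n else ir.t0_ms)
    if t_hi <= t_lo:
        raise ValidationError("red and infrared channels do not overlap in time")

    centers = np.arange(t_lo + window_ms / 2.0, t_hi - window_ms / 2.0 + 1e-9, window_ms / 2.0)
    if centers.size == 0:
        centers = np.array([(t_lo + t_hi) / 2.0])
    values = np.full(centers.size, np.nan)
    for i, c in enumerate(centers):
        try:
            r = _window_ratio(red, ir, c - window_ms / 2.0, c + window_ms / 2.0)
        except ValidationError:
            continue
        if r is not None:
            values[i] = float(np.clip(c0 - c1 * r, 0.0, 100.0))
    if np.all(np.isnan(values)):
        warnings.warn("SpO2: no valid windows (flat PPG or nonpositive DC)")
    return VitalSeries(centers, values, "spo2_pct", window_ms)


def _window_ratio(red: SensorStream, ir: SensorStream, start_ms: float, stop_ms: float):
    def seg(s: SensorStream) -> np.ndarray:
        i0 = int(np.ceil((start_ms - s.t0_ms) / s.dt_ms))
        i1 = int(np.floor((stop_ms - s.t0_ms) / s.dt_ms)) + 1
        return s.samples[max(i0, 0) : max(i1, 0)]

    xr, xi = seg(red), seg(ir)
    if xr.size < red.rate_hz or xi.size < ir.rate_hz:
        return None
    dc_r, dc_i = float(np.nanmean(xr)), float(np.nanmean(xi))
    if dc_r <= 0 or dc_i <= 0:
        return None
    ac_r = _pulse_amplitude(xr, red.rate_hz)
    ac_i = _pulse_amplitude(xi, ir.rate_hz)
    if ac_r is None or ac_i is None or ac_i <= 0:
        return None
    return (ac_r / dc_r) / (ac_i / dc_i)


def _pulse_amplitude(x: np.ndarray, fs: float):
    """Median peak-to-trough amplitude of the pulsatile component."""
    ac = _bandpass(np.nan_to_num(x, nan=np.nanmean(x) if np.isfinite(np.nanmean(x)) else 0.0),
                   fs, 0.5, 8.0)
    if np.ptp(ac) == 0:
        return None
    dist = max(int(round(0.25 * fs)), 1)
    prom = 0.3 * float(np.percentile(np.abs(ac), 90))
    peaks, _ = sps.find_peaks(ac, distance=dist, prominence=prom)
    troughs, _ = sps.find_peaks(-ac, distance=dist, prominence=prom)
    if peaks.size == 0 or troughs.size == 0:
        return None
    amps = []
    for p in peaks:
        prior = troughs[troughs < p]
        if prior.size:
            amps.append(ac[p] - ac[prior[-1]])
    if not amps:
        return None
    return float(np.median(amps))


def respiratory_rate(
    accel_x: SensorStream,
    accel_y: SensorStream,
    ecg: SensorStream | None = None,
    beats: BeatSeries | None = None,
    window_ms: float = 60_000.0,
    band_hz: tuple[float, float] = (0.1, 1.0),
    quality_gate: float = 0.2,
) -> VitalSeries:
    """Respiratory rate by fusing chest-wall motion and ECG-derived respiration.

    Each accelerometer axis is band-passed to the respiratory band and its
    dominant spectral frequency taken as one estimate; R-peak amplitude
    modulation of the ECG provides a third.  Estimates whose spectral peak
    concentrates less than ``quality_gate`` of band power are dropped; the
    fused output is the quality-weighted median of the survivors, in
    breaths/min.  Invariant to DC offset and uniform gain on any axis.
    """
    if window_ms < 30_000.0:
        raise ValidationError("respiratory window must be at least 30 s")
    t_lo = max(accel_x.t0_ms, accel_y.t0_ms)
    t_hi = min(accel_x.times_ms[-1], accel_y.times_ms[-1])
    step = window_ms / 2.0
    centers = np.arange(t_lo + window_ms / 2.0, t_hi - window_ms / 2.0 + 1e-9, step)
    if centers.size == 0:
        centers = np.array([(t_lo + t_hi) / 2.0])

    edr_t, edr_a = _edr_signal(ecg, beats) if (ecg is not None and beats is not None) else (None, None)

    values = np.full(centers.size, np.nan)
    for i, c in enumerate(centers):
        lo, hi = c - window_ms / 2.0, c + window_ms / 2.0
        ests, weights = [], []
        for ax in (accel_x, accel_y):
            est = _dominant_freq_stream(ax, lo, hi, band_hz, quality_gate)
            if est is not None:
                ests.append(est[0] * 60.0)
                weights.append(est[1])
        if edr_t is not None:
            est = _dominant_freq_events(edr_t, edr_a, lo, hi, band_hz, quality_gate)
            if est is not None:
                ests.append(est[0] * 60.0)
                weights.append(est[1])
        if ests:
            values[i] = _weighted_median(np.array(ests), np.array(weights))
    return VitalSeries(centers, values, "rr_brpm", window_ms)


def _edr_signal(ecg: SensorStream, beats: BeatSeries):
    """ECG-derived respiration: R-peak amplitude at each beat time."""
    if beats.n < 3:
        return None, None
    idx = np.round((beats.times_ms - ecg.t0_ms) / ecg.dt_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < ecg.n)]
    amps = ecg.samples[idx]
    return ecg.t0_ms + idx * ecg.dt_ms, amps


def _dominant_freq_stream(s: SensorStream, lo_ms, hi_ms, band, gate):
    i0 = max(int(np.ceil((lo_ms - s.t0_ms) / s.dt_ms)), 0)
    i1 = min(int(np.floor((hi_ms - s.t0_ms) / s.dt_ms)) + 1, s.n)
    x = s.samples[i0:i1]
    if x.size < 8 or np.ptp(np.nan_to_num(x)) == 0:
        return None
    x = np.nan_to_num(x - np.nanmean(x), nan=0.0)
    return _dominant_freq(x, s.rate_hz, band, gate)


def _dominant_freq_events(t_ms, amps, lo_ms, hi_ms, band, gate):
    sel = (t_ms >= lo_ms) & (t_ms <= hi_ms)
    if sel.sum() < 6:
        return None
    # resample the unevenly sampled beat-amplitude series to uniform 4 Hz
    fs = 4.0
    tt = t_ms[sel] / 1000.0
    grid = np.arange(tt[0], tt[-1], 1.0 / fs)
    if grid.size < 8:
        return None
    x = np.interp(grid, tt, amps[sel])
    x -= x.mean()
    if np.ptp(x) == 0:
        return None
    return _dominant_freq(x, fs, band, gate)


def _dominant_freq(x: np.ndarray, fs: float, band, gate):
    freqs, psd = sps.periodogram(x, fs=fs, window="hann")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or psd[sel].sum() <= 0:
        return None
    fsel, psel = freqs[sel], psd[sel]
    k = int(np.argmax(psel))
    concentration = float(psel[k] / psel.sum())
    if concentration < gate:
        return None
    return float(fsel[k]), concentration


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def temperature_series(
    temp: SensorStream, smooth_window_ms: float = 300_000.0
) -> VitalSeries:
    """Moving-median smoothed skin temperature trend.

    Chest (central) and limb (peripheral) channels are smoothed separately
    by the caller; the median window rejects isolated contact artifacts.
    """
    if temp.n == 0:
        return VitalSeries(np.array([]), np.array([]), "temp_c", smooth_window_ms)
    n_win = max(int(round(smooth_window_ms / temp.dt_ms)), 1)
    if n_win % 2 == 0:
        n_win += 1
    if n_win >= temp.n:
        n_win = temp.n if temp.n % 2 == 1 else temp.n - 1
    if n_win >= 3:
        smoothed = sps.medfilt(np.nan_to_num(temp.samples, nan=np.nanmedian(temp.samples)), n_win)
        # medfilt zero-pads the edges; fall back to the raw values there
        half = n_win // 2
        smoothed[:half] = temp.samples[:half]
        smoothed[-half:] = temp.samples[-half:]
    else:
        smoothed = temp.samples.copy()
    return VitalSeries(temp.times_ms, smoothed, "temp_c", smooth_window_ms)
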