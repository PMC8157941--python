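"""Cuffless blood pressure from pulse arrival time (PAT).

PAT is the interval from an ECG R peak to the arrival of the corresponding
pulse wave at the limb PPG; it shortens as arterial pressure rises, so a
per-subject linear map — improved by adding heart rate as a second
regressor — turns PAT into a continuous systolic/diastolic BP surrogate
after calibration against a reference (a continuous monitor for the first
~50 s, or sparse cuff readings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BeatSeries, ValidationError, VitalSeries

__all__ = ["PatSeries", "BpCoefficients", "BpCalibration", "compute_pat",
           "fit_calibration", "predict_bp", "CalibrationError"]


class CalibrationError(ValueError):
    """Raised when the calibration design is degenerate (e.g. constant PAT)."""


@dataclass
class PatSeries:
    """Per-beat pulse arrival time with concurrent heart rate."""

    times_ms: np.ndarray   # R-peak time of each matched beat
    pat_ms: np.ndarray
    hr_bpm: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.pat_ms = np.asarray(self.pat_ms, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.quality is None:
            self.quality = (self.pat_ms > 0) & (self.pat_ms < 1000)

    @property
    def n(self) -> int:
        return int(self.times_ms.size)


@dataclass
class BpCoefficients:
    """BP = a_pat * PAT + b_hr * HR + c.  a_pat < 0 on physiological data."""

    a_pat: float
    b_hr: float
    c: float

    def predict(self, pat_ms: np.ndarray, hr_bpm: np.ndarray) -> np.ndarray:
        return self.a_pat * np.asarray(pat_ms) + self.b_hr * np.asarray(hr_bpm) + self.c


@dataclass
class BpCalibration:
    sbp: BpCoefficients
    dbp: BpCoefficients | None = None
    calib_window_ms: float = 50_000.0
    reference_source: str = "continuous_monitor"  # or "cuff"
    use_hr: bool = True


def compute_pat(r_peaks: BeatSeries, ppg_pulses: BeatSeries) -> PatSeries:
    """Match each R peak to the first PPG pulse strictly after it.

    The pulse must also precede the next R peak; beats with no such pulse
    are skipped.  PAT = pulse time - R time.  The concurrent heart rate is
    taken from the R-R interval ending at the matched beat.
    """
    rt = r_peaks.times_ms
    pt = ppg_pulses.times_ms
    if rt.size == 0 or pt.size == 0 or pt[-1] <= rt[0] or rt[-1] <= pt[0] - 2000:
        raise ValidationError("R-peak and PPG pulse series do not overlap")

    times, pats, hrs = [], [], []
    for i, r in enumerate(rt):
        nxt = rt[i + 1] if i + 1 < rt.size else np.inf
        j = np.searchsorted(pt, r, side="right")  # first pulse strictly after r
        if j >= pt.size or pt[j] >= nxt:
            continue
        rr = rt[i] - rt[i - 1] if i > 0 else (rt[i + 1] - rt[i] if i + 1 < rt.size else np.nan)
        times.append(r)
        pats.append(pt[j] - r)
        hrs.append(60000.0 / rr if np.isfinite(rr) and rr > 0 else np.nan)
    if not times:
        raise ValidationError("no R peak matched a PPG pulse")
    return PatSeries(np.array(times), np.array(pats), np.array(hrs))


def _design(pat: np.ndarray, hr: np.ndarray, use_hr: bool) -> np.ndarray:
    cols = [pat, hr, np.ones_like(pat)] if use_hr else [pat, np.ones_like(pat)]
    return np.column_stack(cols)


def _fit_one(pat, hr, bp, use_hr: bool) -> BpCoefficients:
    X = _design(pat, hr, use_hr)
    # degenerate design: regressors carry no variation
    span = np.ptp(pat) + (np.ptp(hr) if use_hr else 0.0)
    if X.shape[0] < X.shape[1] or span < 1e-9:
        raise CalibrationError("constant PAT/HR: calibration design is rank-deficient")
    coef, *_ = np.linalg.lstsq(X, bp, rcond=None)
    if use_hr:
        return BpCoefficients(float(coef[0]), float(coef[1]), float(coef[2]))
    return BpCoefficients(float(coef[0]), 0.0, float(coef[1]))


def fit_calibration(
    pat: PatSeries,
    reference: pd.DataFrame,
    mode: str = "continuous",
    calib_window_ms: float = 50_000.0,
    use_hr: bool = True,
    cuff_match_tolerance_ms: float = 30_000.0,
) -> BpCalibration:
    """Fit the linear PAT(+HR)→BP map against a reference.

    ``reference`` needs columns ``time_ms`` and ``sbp_mmhg`` (``dbp_mmhg``
    optional; the same model form is applied to both pressures).

    continuous mode: beats inside the first ``calib_window_ms`` of overlap
    are regressed on the reference interpolated to beat times (ordinary
    least squares).

    cuff mode: each cuff reading is matched to the mean PAT/HR within
    ±30 s, all matched readings are fit jointly, and the intercept is then
    offset so the mean residual at the reference times is exactly zero.
    """
    if "time_ms" not in reference.columns or "sbp_mmhg" not in reference.columns:
        raise ValidationError("reference needs time_ms and sbp_mmhg columns")
    good = pat.quality & np.isfinite(pat.hr_bpm) & np.isfinite(pat.pat_ms)
    t, p, h = pat.times_ms[good], pat.pat_ms[good], pat.hr_bpm[good]
    rt = reference["time_ms"].to_numpy(dtype=float)

    targets = {"sbp": "sbp_mmhg"}
    if "dbp_mmhg" in reference.columns:
        targets["dbp"] = "dbp_mmhg"
    fitted: dict[str, BpCoefficients] = {}

    if mode == "continuous":
        t_lo = max(t[0], rt[0])
        t_hi = min(t[-1], rt[-1])
        if t_hi - t_lo < calib_window_ms:
            raise ValidationError(
                f"continuous calibration needs {calib_window_ms/1000:.0f} s of overlap"
            )
        sel = (t >= t_lo) & (t <= t_lo + calib_window_ms)
        if sel.sum() < 3:
            raise ValidationError("too few beats in the calibration window")
        for name, col in targets.items():
            bp_at = np.interp(t[sel], rt, reference[col].to_numpy(dtype=float))
            fitted[name] = _fit_one(p[sel], h[sel], bp_at, use_hr)
    elif mode == "cuff":
        rows = []
        for k in range(rt.size):
            sel = np.abs(t - rt[k]) <= cuff_match_tolerance_ms
            if sel.any():
                rows.append((k, float(np.mean(p[sel])), float(np.mean(h[sel]))))
        if len(rows) < 2:
            raise ValidationError("cuff calibration needs >= 2 matched cuff readings")
        ks = [r[0] for r in rows]
        pm = np.array([r[1] for r in rows])
        hm = np.array([r[2] for r in rows])
        # two cuff readings cannot constrain both PAT and HR terms
        fit_hr = use_hr and len(rows) >= 3
        for name, col in targets.items():
            bp_ref = reference[col].to_numpy(dtype=float)[ks]
            coefs = _fit_one(pm, hm, bp_ref, fit_hr)
            # "necessary offsets": zero the mean residual at reference times
            resid = bp_ref - coefs.predict(pm, hm)
            coefs.c += float(np.mean(resid))
            fitted[name] = coefs
    else:
        raise ValidationError(f"unknown calibration mode {mode!r}")

    return BpCalibration(
        sbp=fitted["sbp"],
        dbp=fitted.get("dbp"),
        calib_window_ms=calib_window_ms,
        reference_source="cuff" if mode == "cuff" else "continuous_monitor",
        use_hr=use_hr,
    )


def predict_bp(
    pat: PatSeries,
    calib: BpCalibration,
    smooth_window_ms: float = 30_000.0,
) -> tuple[VitalSeries, VitalSeries | None]:
    """Continuous SBP (and DBP when calibrated) from per-beat PAT.

    Per-beat linear prediction followed by moving-median smoothing;
    predictions outside 40-280 mmHg become missing rather than clipped.
    """
    good = pat.quality & np.isfinite(pat.pat_ms)
    t = pat.times_ms[good]
    p = pat.pat_ms[good]
    h = np.where(np.isfinite(pat.hr_bpm[good]), pat.hr_bpm[good], np.nanmedian(pat.hr_bpm))

    def series(coefs: BpCoefficients, vital: str) -> VitalSeries:
        raw = coefs.predict(p, h)
        smoothed = _moving_median(t, raw, smooth_window_ms)
        return VitalSeries(t, smoothed, vital, smooth_window_ms, units="mmHg")

    sbp = series(calib.sbp, "sbp_mmhg")
    dbp = series(calib.dbp, "dbp_mmhg") if calib.dbp is not None else None
    return sbp, dbp


def _moving_median(t: np.ndarray, x: np.ndarray, window_ms: float) -> np.ndarray:
    out = np.empty_like(x)
    half = window_ms / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    for i in range(x.size):
        out[i] = np.median(x[lo[i] : hi[i]])
    return out
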