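"""Core data model for multi-sensor maternal-fetal monitoring sessions.

A session is a set of uniformly sampled sensor streams (chest, limb,
abdominal) expressed on a single session clock in milliseconds, plus sparse
reference measurements such as cuff blood pressure.  All event times
downstream (beats, pulses, contractions) are session-relative milliseconds;
the millisecond resolution is required because pulse arrival time is an
interval of order 100-300 ms measured between two different sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "SyncedSession",
    "BeatSeries",
    "VitalSeries",
    "CANONICAL_RATES_HZ",
    "VITAL_RANGES",
    "SENSORS",
    "ValidationError",
    "align",
    "resample",
]

SENSORS = ("chest", "limb", "abdominal", "reference")

#: Native sampling rates of the device streams (Hz).
CANONICAL_RATES_HZ = {
    ("chest", "ecg"): 512.0,
    ("chest", "imu"): 416.0,
    ("chest", "accel"): 52.0,
    ("chest", "temp"): 0.2,
    ("limb", "ppg_red"): 256.0,
    ("limb", "ppg_ir"): 256.0,
    ("limb", "temp"): 0.2,
    ("abdominal", "doppler"): 504.0,
    ("abdominal", "ehg1"): 500.0,
    ("abdominal", "ehg2"): 500.0,
    ("abdominal", "ecg"): 500.0,
}

#: Physiological plausibility bounds per derived vital.  Values outside the
#: bound become missing (NaN), never silently clipped — except the SpO2 upper
#: bound, which is a hard physical ceiling of the ratio-of-ratios mapping.
VITAL_RANGES = {
    "hr_bpm": (20.0, 300.0),
    "fhr_bpm": (60.0, 240.0),
    "spo2_pct": (0.0, 100.0),
    "rr_brpm": (2.0, 80.0),
    "temp_c": (25.0, 45.0),
    "sbp_mmhg": (40.0, 280.0),
    "dbp_mmhg": (40.0, 280.0),
}

MAX_ALIGN_OFFSET_MS = 60_000.0


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class SensorStream:
    """One uniformly sampled channel.

    Sample ``i`` occurs at ``t0_ms + i * 1000 / rate_hz`` on the session
    clock.  Missing samples are encoded as NaN; downstream operations must
    skip, never interpolate across, gaps longer than two sample periods.
    """

    label: str
    sensor: str
    rate_hz: float
    samples: np.ndarray
    t0_ms: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValidationError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.sensor not in SENSORS:
            raise ValidationError(f"unknown sensor {self.sensor!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.n * self.dt_ms

    @property
    def key(self) -> tuple[str, str]:
        return (self.sensor, self.label)

    def shifted(self, offset_ms: float) -> "SensorStream":
        return replace(self, t0_ms=self.t0_ms + float(offset_ms))

    def allclose(self, other: "SensorStream", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        return (
            self.key == other.key
            and np.isclose(self.rate_hz, other.rate_hz, rtol=rtol)
            and np.isclose(self.t0_ms, other.t0_ms, rtol=rtol, atol=atol)
            and self.n == other.n
            and np.allclose(self.samples, other.samples, rtol=rtol, atol=atol, equal_nan=True)
        )


@dataclass
class SyncedSession:
    """A set of streams on one session clock plus sparse reference readings.

    ``references`` is a DataFrame with a ``time_ms`` column and one column
    per reference quantity (e.g. ``sbp_mmhg``, ``dbp_mmhg`` from a cuff).
    ``sync_tolerance_ms`` is the residual inter-sensor clock skew the
    on-body synchronization protocol guarantees (1 ms for this device).
    """

    streams: list[SensorStream] = field(default_factory=list)
    references: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame({"time_ms": pd.Series(dtype=float)})
    )
    sync_tolerance_ms: float = 1.0

    def __post_init__(self) -> None:
        keys = [s.key for s in self.streams]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValidationError(f"duplicate (sensor, label) streams: {sorted(dupes)}")
        if "time_ms" not in self.references.columns:
            raise ValidationError("references must have a time_ms column")

    def get(self, sensor: str, label: str) -> SensorStream:
        for s in self.streams:
            if s.key == (sensor, label):
                return s
        raise KeyError(f"no stream ({sensor}, {label}); have {[s.key for s in self.streams]}")

    def has(self, sensor: str, label: str) -> bool:
        return any(s.key == (sensor, label) for s in self.streams)

    def sensors(self) -> set[str]:
        return {s.sensor for s in self.streams}


@dataclass
class BeatSeries:
    """Detected event times (ms, session clock) with per-event quality.

    ``quality`` holds True for good events, False for suspect ones (e.g. an
    R-R interval outside the physiological 250-2000 ms band, or a detection
    made at low local signal-to-noise ratio).
    """

    times_ms: np.ndarray
    kind: str = "r_peak"
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.quality is None:
            self.quality = np.ones(self.times_ms.size, dtype=bool)
        else:
            self.quality = np.asarray(self.quality, dtype=bool)
        if self.quality.size != self.times_ms.size:
            raise ValidationError("quality must be per-event")
        if self.times_ms.size > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValidationError("beat times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times_ms.size)

    def good_times(self) -> np.ndarray:
        return self.times_ms[self.quality]

    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.times_ms)


@dataclass
class VitalSeries:
    """Timestamped derived values of one vital sign.

    ``values`` are unrounded; clinical display rounding (integer HR/RR,
    one-decimal SpO2) is applied only by :meth:`display_values`.
    Out-of-range values are NaN.
    """

    times_ms: np.ndarray
    values: np.ndarray
    vital: str
    window_ms: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ms.size != self.values.size:
            raise ValidationError("times and values must have equal length")
        lo, hi = VITAL_RANGES.get(self.vital, (-np.inf, np.inf))
        out = (self.values < lo) | (self.values > hi)
        if out.any():
            self.values = np.where(out, np.nan, self.values)

    @property
    def n(self) -> int:
        return int(self.times_ms.size)

    def display_values(self) -> np.ndarray:
        if self.vital in ("hr_bpm", "fhr_bpm", "rr_brpm"):
            return np.round(self.values)
        if self.vital == "spo2_pct":
            return np.round(self.values, 1)
        return self.values

    def dropna(self) -> "VitalSeries":
        keep = np.isfinite(self.values)
        return VitalSeries(
            self.times_ms[keep], self.values[keep], self.vital, self.window_ms, self.units
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times_ms, "vital": self.vital, "value": self.values}
        )


def align(session: SyncedSession, offsets: Mapping[str, float]) -> SyncedSession:
    """Shift each sensor's streams by its clock offset (ms).

    Models removal of residual inter-sensor clock skew: the stream start
    times move, the sparse references (already on the session clock) do not.
    ``align(align(s, a), b) == align(s, a + b)`` and zero offsets are the
    identity.
    """
    for sensor, off in offsets.items():
        if abs(off) >= MAX_ALIGN_OFFSET_MS:
            raise ValidationError(
                f"offset for {sensor!r} is {off} ms; |offset| must be < 60 s"
            )
    streams = [s.shifted(offsets.get(s.sensor, 0.0)) for s in session.streams]
    return SyncedSession(streams, session.references.copy(), session.sync_tolerance_ms)


def resample(stream: SensorStream, target_hz: float) -> SensorStream:
    """Linear-interpolation resampling on the closed original time span."""
    if target_hz <= 0:
        raise ValidationError("target_hz must be positive")
    if stream.n == 0:
        raise ValidationError("cannot resample an empty stream")
    if np.isclose(target_hz, stream.rate_hz):
        return replace(stream)
    old_t = stream.times_ms
    new_dt = 1000.0 / target_hz
    n_new = int(np.floor((old_t[-1] - old_t[0]) / new_dt)) + 1
    new_t = old_t[0] + np.arange(n_new) * new_dt
    new_samples = np.interp(new_t, old_t, stream.samples)
    return SensorStream(
        label=stream.label,
        sensor=stream.sensor,
        rate_hz=float(target_hz),
        samples=new_samples,
        t0_ms=stream.t0_ms,
        units=stream.units,
    )


def crop(stream: SensorStream, start_ms: float, stop_ms: float) -> SensorStream:
    """Return the sub-stream whose samples fall in [start_ms, stop_ms]."""
    t = stream.times_ms
    i0, i1 = np.searchsorted(t, [start_ms, stop_ms], side="left")
    if i1 < stream.n and t[i1] <= stop_ms:
        i1 += 1
    return replace(stream, samples=stream.samples[i0:i1], t0_ms=float(t[i0]) if i1 > i0 else stream.t0_ms)
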