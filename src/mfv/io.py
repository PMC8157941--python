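"""Session file I/O: EDF and long-format CSV for waveforms, CSV for sparse
references and derived vitals, WAV for Doppler audio export.

CSV dialect for waveforms is long format with header
``time_ms,sensor,channel,value,units`` (UTF-8).  Reference (cuff) readings
are carried in the same file under ``sensor == "reference"``.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import edf as _edf
from .core import (
    CANONICAL_RATES_HZ,
    SensorStream,
    SyncedSession,
    ValidationError,
)

__all__ = [
    "read_session",
    "write_session",
    "read_references",
    "write_vitals",
    "export_wav",
    "DEFAULT_ALIASES",
]

#: Channel-label aliases → canonical (sensor, label).  Extend via the
#: ``aliases`` argument of :func:`read_session` for foreign recordings.
DEFAULT_ALIASES = {
    "ecg": ("chest", "ecg"),
    "ekg": ("chest", "ecg"),
    "accel_x": ("chest", "accel_x"),
    "accel_y": ("chest", "accel_y"),
    "accel_z": ("chest", "accel_z"),
    "temp": ("chest", "temp"),
    "ppg_red": ("limb", "ppg_red"),
    "ppg_ir": ("limb", "ppg_ir"),
    "doppler": ("abdominal", "doppler"),
    "ehg1": ("abdominal", "ehg1"),
    "ehg2": ("abdominal", "ehg2"),
    "abd_ecg": ("abdominal", "ecg"),
}


def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix in (".edf", ".rec"):
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise IOError(f"cannot infer format from {path}; pass format='edf' or 'csv'")


def read_session(path, format: str | None = None, aliases: dict | None = None) -> SyncedSession:
    """Read a multi-channel recording into a :class:`SyncedSession`.

    Channel labels are mapped onto the canonical (sensor, label) set through
    an alias table; unknown channels are preserved under the sensor named in
    the file (or ``chest``) with a warning.
    """
    fmt = _infer_format(path, format)
    amap = dict(DEFAULT_ALIASES)
    if aliases:
        amap.update(aliases)

    if fmt == "edf":
        return _read_edf_session(path, amap)
    if fmt == "csv":
        return _read_csv_session(path, amap)
    raise IOError(f"unsupported format {fmt!r}")


def _resolve(sensor_hint: str, label: str, amap: dict) -> tuple[str, str]:
    key = label.strip().lower()
    # an explicit, valid (sensor, label) pair wins over the alias table —
    # e.g. "ecg" exists on both the chest and the abdominal sensor
    if (sensor_hint, key) in CANONICAL_RATES_HZ:
        return sensor_hint, key
    if key in amap:
        return amap[key]
    sensor = sensor_hint if sensor_hint in ("chest", "limb", "abdominal") else "chest"
    if (sensor, key) not in CANONICAL_RATES_HZ and not re.match(r"accel_[xyz]$", key):
        warnings.warn(f"unknown channel {label!r}; preserved under sensor {sensor!r}")
    return sensor, key


def _read_edf_session(path, amap: dict) -> SyncedSession:
    channels = _edf.read_edf(path)
    streams = []
    for ch in channels:
        sensor, label = _resolve(ch.transducer.strip().lower(), ch.label, amap)
        m = re.search(r"t0_ms=([-\d.eE+]+)", ch.prefilter)
        t0 = float(m.group(1)) if m else 0.0
        streams.append(
            SensorStream(
                label=label,
                sensor=sensor,
                rate_hz=ch.rate_hz,
                samples=ch.samples,
                t0_ms=t0,
                units=ch.units,
            )
        )
    return SyncedSession(streams=streams)


def _read_csv_session(path, amap: dict) -> SyncedSession:
    df = pd.read_csv(path)
    required = {"time_ms", "sensor", "channel", "value"}
    if not required.issubset(df.columns):
        raise IOError(f"CSV must have columns {sorted(required)}; got {list(df.columns)}")
    if "units" not in df.columns:
        df["units"] = ""
    df["units"] = df["units"].fillna("")

    streams: list[SensorStream] = []
    refs = df[df["sensor"] == "reference"]
    wave = df[df["sensor"] != "reference"]
    seen = set()
    for (sensor, channel), grp in wave.groupby(["sensor", "channel"], sort=False):
        sensor2, label = _resolve(str(sensor), str(channel), amap)
        if (sensor2, label) in seen:
            raise IOError(f"duplicate channel ({sensor2}, {label}) in {path}")
        seen.add((sensor2, label))
        grp = grp.sort_values("time_ms")
        t = grp["time_ms"].to_numpy(dtype=float)
        if t.size > 1:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise IOError(f"non-increasing timestamps for channel {channel!r}")
            rate = 1000.0 / dt
        else:
            rate = CANONICAL_RATES_HZ.get((sensor2, label), 1.0)
        streams.append(
            SensorStream(
                label=label,
                sensor=sensor2,
                rate_hz=float(rate),
                samples=grp["value"].to_numpy(dtype=float),
                t0_ms=float(t[0]) if t.size else 0.0,
                units=str(grp["units"].iloc[0]) if len(grp) else "",
            )
        )

    references = pd.DataFrame({"time_ms": pd.Series(dtype=float)})
    if len(refs):
        references = (
            refs.pivot_table(index="time_ms", columns="channel", values="value")
            .reset_index()
            .rename_axis(None, axis=1)
        )
    return SyncedSession(streams=streams, references=references)


def write_session(session: SyncedSession, path, format: str | None = None) -> None:
    """Write a session to EDF (waveforms only) or long-format CSV."""
    fmt = _infer_format(path, format)
    if fmt == "edf":
        channels = [
            _edf.EdfChannel(
                label=s.label,
                transducer=s.sensor,
                units=s.units,
                rate_hz=s.rate_hz,
                samples=s.samples,
                prefilter=f"t0_ms={s.t0_ms:.6f}",
            )
            for s in session.streams
        ]
        _edf.write_edf(path, channels)
        return
    if fmt == "csv":
        frames = [
            pd.DataFrame(
                {
                    "time_ms": s.times_ms,
                    "sensor": s.sensor,
                    "channel": s.label,
                    "value": s.samples,
                    "units": s.units,
                }
            )
            for s in session.streams
        ]
        refs = session.references
        if len(refs):
            for col in refs.columns:
                if col == "time_ms":
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "time_ms": refs["time_ms"],
                            "sensor": "reference",
                            "channel": col,
                            "value": refs[col],
                            "units": "",
                        }
                    )
                )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return
    raise IOError(f"unsupported format {fmt!r}")


def read_references(path) -> pd.DataFrame:
    """Read a timestamped sparse reference CSV (e.g. cuff BP readings).

    Expected columns: ``time_ms`` plus one column per quantity, e.g.
    ``sbp_mmhg, dbp_mmhg``.
    """
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise IOError("reference CSV must have a time_ms column")
    return df.sort_values("time_ms").reset_index(drop=True)


def write_vitals(series_list, path) -> None:
    """Write derived vitals as tidy CSV (time_ms, vital, value)."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def export_wav(path, samples: np.ndarray, rate_hz: float) -> None:
    """Write 16-bit PCM WAV at the given rate (used for Doppler audio)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot export empty audio")
    pcm = np.round(np.clip(x, -1.0, 1.0) * 32767).astype(np.int16)
    wavfile.write(path, int(round(rate_hz)), pcm)


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a WAV file back to float samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        return float(rate), data.astype(float) / 32767.0
    return float(rate), data.astype(float)
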