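"""Minimal EDF (European Data Format) reader/writer.

Implements the subset of EDF needed to carry multi-rate biosignal channels
in one file: ASCII fixed-width headers and 16-bit little-endian samples with
per-channel physical scaling.  No installed package in the target
environment provides EDF I/O, so this module implements the container
directly from the published format layout.

Conventions used when writing (all inside standard header fields, so files
remain readable by third-party EDF tools):

* the 80-char transducer field stores the sensor name (``chest`` etc.);
* the 80-char prefiltering field stores ``t0_ms=<float>`` so streams with
  different session-clock start times survive a round trip;
* the 32-char per-channel reserved field stores ``n=<int>``, the true
  sample count before padding to a whole number of data records.

Precision is limited by 16-bit quantization of the physical range.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = ["read_edf", "write_edf", "EdfChannel", "EdfError"]

_HDR = 256  # bytes, fixed part and per-channel part


class EdfError(IOError):
    pass


@dataclass
class EdfChannel:
    label: str
    transducer: str
    units: str
    rate_hz: float
    samples: np.ndarray
    prefilter: str = ""
    n_true: int | None = None


def _fw(text: str, width: int) -> bytes:
    """Fixed-width ASCII field, space padded, truncated if needed."""
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _ascii8(v: float) -> str:
    """Shortest decimal representation of ``v`` fitting 8 characters."""
    for prec in range(7, 0, -1):
        s = "%.*g" % (prec, v)
        if len(s) <= 8:
            return s
    return ("%.1g" % v)[:8]


def _bound8(v: float, direction: int) -> float:
    """8-char-representable value on the ``direction`` side of ``v``."""
    s = float(_ascii8(v))
    step = max(abs(v), 1e-30) * 1e-6
    while (direction < 0 and s > v) or (direction > 0 and s < v):
        v = v + direction * step
        step *= 10.0
        s = float(_ascii8(v))
    return s


def _record_duration(rates: list[float]) -> float:
    """Smallest duration in a practical set giving integer samples/record."""
    for d in (1.0, 2.0, 5.0, 10.0, 30.0, 60.0):
        if all(abs(r * d - round(r * d)) < 1e-9 and round(r * d) >= 1 for r in rates):
            return d
    raise EdfError(f"no record duration up to 60 s fits rates {rates}")


def write_edf(path, channels: list[EdfChannel], start: _dt.datetime | None = None) -> None:
    if not channels:
        raise EdfError("no channels to write")
    rates = [c.rate_hz for c in channels]
    dur = _record_duration(rates)
    spr = [int(round(c.rate_hz * dur)) for c in channels]  # samples per record
    n_rec = max(
        int(math.ceil(c.samples.size / s)) if c.samples.size else 1
        for c, s in zip(channels, spr)
    )
    start = start or _dt.datetime(2000, 1, 1)

    ns = len(channels)
    header_bytes = _HDR + ns * _HDR
    parts = [
        _fw("0", 8),
        _fw("X X X X", 80),
        _fw("Startdate X X X X", 80),
        _fw(start.strftime("%d.%m.%y"), 8),
        _fw(start.strftime("%H.%M.%S"), 8),
        _fw(str(header_bytes), 8),
        _fw("", 44),
        _fw(str(n_rec), 8),
        _fw(("%g" % dur), 8),
        _fw(str(ns), 4),
    ]

    phys_lo, phys_hi, dig_lo, dig_hi = [], [], [], []
    data_int = []
    for c in channels:
        x = np.asarray(c.samples, dtype=float)
        finite = x[np.isfinite(x)]
        lo = float(finite.min()) if finite.size else -1.0
        hi = float(finite.max()) if finite.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        # use the 8-char header representation the reader will parse, so
        # scaling is consistent across the round trip; widen outward so no
        # sample falls outside the written physical range
        lo = _bound8(lo, -1)
        hi = _bound8(hi, +1)
        dlo, dhi = -32768, 32767
        scale = (dhi - dlo) / (hi - lo)
        filled = np.where(np.isfinite(x), x, lo)  # NaN -> physical minimum
        d = np.round((filled - lo) * scale + dlo).astype("<i2")
        phys_lo.append(lo)
        phys_hi.append(hi)
        dig_lo.append(dlo)
        dig_hi.append(dhi)
        data_int.append(d)

    for fld, width in (
        ([c.label for c in channels], 16),
        ([c.transducer for c in channels], 80),
        ([c.units for c in channels], 8),
        ([_ascii8(v) for v in phys_lo], 8),
        ([_ascii8(v) for v in phys_hi], 8),
        ([str(v) for v in dig_lo], 8),
        ([str(v) for v in dig_hi], 8),
        ([c.prefilter for c in channels], 80),
        ([str(s) for s in spr], 8),
        (["n=%d" % c.samples.size for c in channels], 32),
    ):
        parts.extend(_fw(v, width) for v in fld)

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for r in range(n_rec):
            for d, s in zip(data_int, spr):
                seg = d[r * s : (r + 1) * s]
                if seg.size < s:  # pad final record with the last value
                    pad_val = seg[-1] if seg.size else np.int16(0)
                    seg = np.concatenate([seg, np.full(s - seg.size, pad_val, dtype="<i2")])
                fh.write(seg.astype("<i2").tobytes())


def read_edf(path) -> list[EdfChannel]:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise EdfError("file too short for an EDF header")

    def f(o, w):
        return raw[o : o + w].decode("ascii", "replace").strip()

    try:
        n_rec = int(f(236, 8))
        dur = float(f(244, 8))
        ns = int(f(252, 4))
    except ValueError as e:
        raise EdfError(f"malformed EDF header: {e}") from None

    off = _HDR

    def col(width):
        nonlocal off
        vals = [f(off + i * width, width) for i in range(ns)]
        off += ns * width
        return vals

    labels = col(16)
    transducers = col(80)
    units = col(8)
    phys_lo = [float(v) for v in col(8)]
    phys_hi = [float(v) for v in col(8)]
    dig_lo = [int(v) for v in col(8)]
    dig_hi = [int(v) for v in col(8)]
    prefilter = col(80)
    spr = [int(v) for v in col(8)]
    reserved = col(32)

    data = np.frombuffer(raw[_HDR + ns * _HDR :], dtype="<i2")
    rec_len = sum(spr)
    if data.size < n_rec * rec_len:
        raise EdfError("truncated EDF data section")
    data = data[: n_rec * rec_len].reshape(n_rec, rec_len)

    channels = []
    pos = 0
    for i in range(ns):
        d = data[:, pos : pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        gain = (phys_hi[i] - phys_lo[i]) / (dig_hi[i] - dig_lo[i])
        x = (d - dig_lo[i]) * gain + phys_lo[i]
        m = re.match(r"n=(\d+)", reserved[i])
        n_true = int(m.group(1)) if m else None
        if n_true is not None:
            x = x[:n_true]
        channels.append(
            EdfChannel(
                label=labels[i],
                transducer=transducers[i],
                units=units[i],
                rate_hz=spr[i] / dur,
                samples=x,
                prefilter=prefilter[i],
                n_true=n_true,
            )
        )
    return channels
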