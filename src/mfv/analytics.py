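"""Device-agreement statistics and session/population summaries.

Bland-Altman analysis quantifies agreement between the wearable output and
a reference monitor: the mean of paired differences gives the bias, and
mean ± 1.96 x SD the 95% limits of agreement.  The time-to-vital heat map
pools many labor sessions into a 2-D (session time x vital value) density,
with a second matrix re-normalized inside each 4-hour window so long labors
remain visible despite most sessions ending before 5 hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SyncedSession, ValidationError, VitalSeries

__all__ = [
    "BlandAltmanResult",
    "VitalHeatmap",
    "bland_altman",
    "time_to_vital_heatmap",
    "session_report",
    "DEFAULT_VALUE_BIN",
]

#: Default value-bin width per vital for the heat map.
DEFAULT_VALUE_BIN = {
    "hr_bpm": 1.0,
    "fhr_bpm": 1.0,
    "spo2_pct": 1.0,
    "rr_brpm": 1.0,
    "sbp_mmhg": 2.0,
    "dbp_mmhg": 2.0,
    "temp_c": 0.1,
}


@dataclass
class BlandAltmanResult:
    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pair_means: np.ndarray
    pair_diffs: np.ndarray


def bland_altman(
    device: VitalSeries,
    reference: VitalSeries,
    pairing_tolerance_ms: float = 5000.0,
) -> BlandAltmanResult:
    """Bland-Altman agreement between a device series and a reference.

    Pairs are matched nearest-neighbor in time within the tolerance, each
    reference point used at most once (ties resolved to the closest device
    point).  Differences are device - reference; limits of agreement are
    mean ± 1.96 x sample SD (n-1 denominator).
    """
    dv = device.dropna()
    rv = reference.dropna()
    if dv.n == 0 or rv.n == 0:
        raise ValidationError("need non-empty device and reference series")

    # candidate match: nearest reference for every device point
    j = np.clip(np.searchsorted(rv.times_ms, dv.times_ms), 0, rv.n - 1)
    left = np.clip(j - 1, 0, rv.n - 1)
    use_left = np.abs(rv.times_ms[left] - dv.times_ms) < np.abs(rv.times_ms[j] - dv.times_ms)
    j = np.where(use_left, left, j)
    dist = np.abs(rv.times_ms[j] - dv.times_ms)
    ok = dist <= pairing_tolerance_ms

    # one device point per reference point: keep the closest claimant
    best: dict[int, int] = {}
    for i in np.flatnonzero(ok):
        r = int(j[i])
        if r not in best or dist[i] < dist[best[r]]:
            best[r] = i
    if len(best) < 2:
        raise ValidationError("fewer than 2 matched pairs within tolerance")

    ridx = np.array(sorted(best))
    didx = np.array([best[r] for r in ridx])
    d = dv.values[didx] - rv.values[ridx]
    m = 0.5 * (dv.values[didx] + rv.values[ridx])
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        n_pairs=int(d.size),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pair_means=m,
        pair_diffs=d,
    )


@dataclass
class VitalHeatmap:
    vital: str
    time_edges_ms: np.ndarray
    value_edges: np.ndarray
    counts: np.ndarray       # (n_value_bins, n_time_bins)
    normalized: np.ndarray   # per 4-h window block normalization
    window_h: float


def time_to_vital_heatmap(
    sessions: list[VitalSeries],
    vital: str | None = None,
    time_bin_min: float = 5.0,
    value_bin: float | None = None,
    window_h: float = 4.0,
    max_h: float = 24.0,
) -> VitalHeatmap:
    """Pool sessions into a (session time, vital value) 2-D histogram.

    Session time is each session's own clock (time since its first stream
    sample), so early labor aligns across participants.  The normalized
    matrix divides each 4-hour block of time columns by the block total, so
    every populated block sums to 1 and sparsely attended late-labor hours
    are not swamped by the dense first hours.
    """
    sessions = [s for s in sessions if s.n > 0]
    if not sessions:
        raise ValidationError("no sessions to pool")
    vital = vital or sessions[0].vital
    vb = value_bin if value_bin is not None else DEFAULT_VALUE_BIN.get(vital, 1.0)

    t_all = np.concatenate([s.times_ms for s in sessions])
    v_all = np.concatenate([s.values for s in sessions])
    keep = np.isfinite(v_all) & (t_all <= max_h * 3_600_000.0)
    t_all, v_all = t_all[keep], v_all[keep]
    if t_all.size == 0:
        raise ValidationError("no finite samples to pool")

    time_edges = np.arange(0.0, max_h * 3_600_000.0 + 1, time_bin_min * 60_000.0)
    v_lo = np.floor(v_all.min() / vb) * vb
    v_hi = np.ceil(v_all.max() / vb) * vb + vb
    value_edges = np.arange(v_lo, v_hi + vb / 2, vb)

    counts, _, _ = np.histogram2d(v_all, t_all, bins=(value_edges, time_edges))

    normalized = np.zeros_like(counts)
    cols_per_window = int(round(window_h * 60.0 / time_bin_min))
    for c0 in range(0, counts.shape[1], cols_per_window):
        block = counts[:, c0 : c0 + cols_per_window]
        total = block.sum()
        if total > 0:
            normalized[:, c0 : c0 + cols_per_window] = block / total

    return VitalHeatmap(
        vital=vital,
        time_edges_ms=time_edges,
        value_edges=value_edges,
        counts=counts,
        normalized=normalized,
        window_h=window_h,
    )


_PANELS = (
    ("hr_bpm", "Maternal heart rate"),
    ("spo2_pct", "Oxygen saturation"),
    ("rr_brpm", "Respiratory rate"),
    ("temp_c", "Temperature"),
    ("fhr_bpm", "Fetal heart rate"),
    ("sbp_mmhg", "Systolic blood pressure"),
    ("dbp_mmhg", "Diastolic blood pressure"),
)


def session_report(
    session: SyncedSession,
    derived: dict,
) -> str:
    """Render a deterministic Markdown session report.

    ``derived`` may contain VitalSeries under their vital names, plus
    optional ``postures`` (PostureSeries), ``contractions`` (event list),
    and ``tocogram``.  Panels whose inputs are absent are marked absent
    rather than failing.
    """
    lines = ["# Session report", ""]
    lines.append("## Streams")
    for s in sorted(session.streams, key=lambda s: s.key):
        lines.append(
            f"- {s.sensor}/{s.label}: {s.rate_hz:g} Hz, {s.n} samples, "
            f"{s.duration_ms / 1000.0:.1f} s"
        )
    lines.append("")

    lines.append("## Vitals")
    for vital, title in _PANELS:
        vs = derived.get(vital)
        if vs is None or getattr(vs, "n", 0) == 0:
            lines.append(f"- {title}: absent")
            continue
        finite = np.isfinite(vs.values)
        if finite.any():
            lines.append(
                f"- {title}: n={int(finite.sum())}, "
                f"mean={np.mean(vs.values[finite]):.2f}, "
                f"min={np.min(vs.values[finite]):.2f}, "
                f"max={np.max(vs.values[finite]):.2f}"
            )
        else:
            lines.append(f"- {title}: all values missing")
    lines.append("")

    lines.append("## Uterine activity")
    contractions = derived.get("contractions")
    if contractions is None:
        lines.append("- tocogram: absent")
    else:
        lines.append(f"- contractions detected: {len(contractions)}")
        for ev in contractions:
            lines.append(
                f"  - onset {ev.onset_ms / 1000.0:.0f} s, peak {ev.peak_ms / 1000.0:.0f} s, "
                f"duration {ev.duration_s:.0f} s, amplitude {ev.amplitude:.2f} {ev.units}"
            )
    lines.append("")

    lines.append("## Posture")
    postures = derived.get("postures")
    if postures is None or postures.n == 0:
        lines.append("- posture timeline: absent")
    else:
        labels, counts = np.unique(postures.labels, return_counts=True)
        total = counts.sum()
        for lab, cnt in sorted(zip(labels, counts), key=lambda lc: -lc[1]):
            lines.append(f"- {lab}: {100.0 * cnt / total:.1f}% of session")
    lines.append("")

    lines.append("## Quality")
    n_missing = sum(
        int(np.sum(~np.isfinite(vs.values)))
        for vs in derived.values()
        if isinstance(vs, VitalSeries)
    )
    lines.append(f"- missing derived values: {n_missing}")
    lines.append(f"- sync tolerance: {session.sync_tolerance_ms:g} ms")
    return "\n".join(lines) + "\n"
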