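"""Body-posture classification from chest tri-axial accelerometry.

During quiet (low-motion) periods the accelerometer reads the gravity
vector in the sensor frame, so body orientation clusters tightly in
(x, y, z) space.  A Gaussian mixture with 8 components is fit on up to
50,000 randomly sampled low-motion points; the 8 clusters are then merged
into the four labor postures (supine, lateral, hands-knees, high Fowler's)
by assigning each cluster mean to the nearest canonical gravity direction.
The canonical directions assume a chest-mounted sensor with +z pointing
out of the chest; remap them for other mounting conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .core import SensorStream, ValidationError, VitalSeries

__all__ = [
    "POSTURES",
    "CANONICAL_DIRECTIONS",
    "PostureModel",
    "PostureSeries",
    "fit_posture_model",
    "classify_posture",
    "posture_vital_summary",
]

POSTURES = ("supine", "lateral", "hands_knees", "high_fowlers")

_SQ2 = np.sqrt(0.5)
#: Gravity direction (unit vector, sensor frame) for each posture.  Lateral
#: has two entries because left and right lateral are mirror orientations.
CANONICAL_DIRECTIONS: dict[str, list[tuple[float, float, float]]] = {
    "supine": [(0.0, 0.0, -1.0)],
    "lateral": [(1.0, 0.0, 0.0), (-1.0, 0.0, 0.0)],
    "hands_knees": [(0.0, 0.0, 1.0)],
    "high_fowlers": [(0.0, -_SQ2, -_SQ2)],  # torso elevated >= 45 degrees
}


@dataclass
class PostureModel:
    """Fitted mixture plus the cluster→posture merge map."""

    n_clusters: int
    means: np.ndarray          # (k, 3)
    covariances: np.ndarray    # (k, 3, 3)
    weights: np.ndarray        # (k,)
    cluster_to_posture: list[str]
    sample_budget: int = 50_000
    seed: int = 0
    confidence_threshold: float = 0.6

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_clusters": self.n_clusters,
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "weights": self.weights.tolist(),
                "cluster_to_posture": self.cluster_to_posture,
                "sample_budget": self.sample_budget,
                "seed": self.seed,
                "confidence_threshold": self.confidence_threshold,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PostureModel":
        d = json.loads(text)
        return cls(
            n_clusters=d["n_clusters"],
            means=np.asarray(d["means"]),
            covariances=np.asarray(d["covariances"]),
            weights=np.asarray(d["weights"]),
            cluster_to_posture=list(d["cluster_to_posture"]),
            sample_budget=d["sample_budget"],
            seed=d["seed"],
            confidence_threshold=d["confidence_threshold"],
        )


@dataclass
class PostureSeries:
    times_ms: np.ndarray
    labels: np.ndarray      # posture names, or "unknown"
    confidence: np.ndarray  # posterior probability of the assigned cluster

    @property
    def n(self) -> int:
        return int(self.times_ms.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times_ms, "posture": self.labels, "confidence": self.confidence}
        )


def _stack_xyz(accel_x: SensorStream, accel_y: SensorStream, accel_z: SensorStream) -> np.ndarray:
    n = min(accel_x.n, accel_y.n, accel_z.n)
    return np.column_stack(
        [accel_x.samples[:n], accel_y.samples[:n], accel_z.samples[:n]]
    )


def _normalize_gravity(xyz: np.ndarray) -> np.ndarray:
    """Scale so the median magnitude is 1 g (gain invariance)."""
    mag = np.linalg.norm(xyz, axis=1)
    scale = np.median(mag[np.isfinite(mag) & (mag > 0)])
    if not np.isfinite(scale) or scale <= 0:
        raise ValidationError("accelerometer magnitude is degenerate")
    return xyz / scale


def _motion_mask(xyz: np.ndarray, rate_hz: float,
                 window_s: float = 2.0, var_threshold: float = 0.02) -> np.ndarray:
    """True where windowed accel-magnitude variance is below threshold (g^2)."""
    mag = np.linalg.norm(xyz, axis=1)
    n = max(int(round(window_s * rate_hz)), 1)
    kernel = np.ones(n) / n
    mean = np.convolve(mag, kernel, mode="same")
    var = np.convolve(mag**2, kernel, mode="same") - mean**2
    return var < var_threshold


def fit_posture_model(
    accel_x: SensorStream,
    accel_y: SensorStream,
    accel_z: SensorStream,
    n_clusters: int = 8,
    sample_budget: int = 50_000,
    seed: int = 0,
    motion_var_threshold: float = 0.02,
    canonical: dict | None = None,
    n_init: int = 10,
) -> PostureModel:
    """Fit the 8-cluster orientation mixture on low-motion samples.

    Deterministic given the seed (seeded subsampling, k-means++ init with
    10 restarts, EM tolerance 1e-6, full covariances).
    """
    xyz = _normalize_gravity(_stack_xyz(accel_x, accel_y, accel_z))
    still = _motion_mask(xyz, accel_x.rate_hz, var_threshold=motion_var_threshold)
    pts = xyz[still & np.isfinite(xyz).all(axis=1)]
    if pts.shape[0] < n_clusters * 50:
        raise ValidationError(
            f"need >= {n_clusters * 50} low-motion samples, got {pts.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    if pts.shape[0] > sample_budget:
        pts = pts[rng.choice(pts.shape[0], sample_budget, replace=False)]

    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        n_init=n_init,
        init_params="k-means++",
        tol=1e-6,
        reg_covar=1e-6,
        random_state=seed,
        max_iter=500,
    ).fit(pts)

    mapping = [_nearest_posture(m, canonical or CANONICAL_DIRECTIONS) for m in gmm.means_]
    if len(set(mapping)) == 1:
        warnings.warn(
            f"all clusters merge to {mapping[0]!r}: the record covers a single orientation"
        )
    return PostureModel(
        n_clusters=n_clusters,
        means=gmm.means_.copy(),
        covariances=gmm.covariances_.copy(),
        weights=gmm.weights_.copy(),
        cluster_to_posture=mapping,
        sample_budget=sample_budget,
        seed=seed,
    )


def _nearest_posture(mean: np.ndarray, canonical: dict) -> str:
    v = mean / (np.linalg.norm(mean) + 1e-12)
    best, best_cos = POSTURES[0], -np.inf
    for posture, dirs in canonical.items():
        for d in dirs:
            cos = float(np.dot(v, np.asarray(d)))
            if cos > best_cos:
                best, best_cos = posture, cos
    return best


def _posteriors(model: PostureModel, xyz: np.ndarray) -> np.ndarray:
    gmm = GaussianMixture(n_components=model.n_clusters, covariance_type="full")
    gmm.means_ = model.means
    gmm.covariances_ = model.covariances
    gmm.weights_ = model.weights
    gmm.precisions_cholesky_ = np.linalg.cholesky(np.linalg.inv(model.covariances))
    return gmm.predict_proba(xyz)


def classify_posture(
    accel_x: SensorStream,
    accel_y: SensorStream,
    accel_z: SensorStream,
    model: PostureModel,
    median_filter_s: float = 5.0,
) -> PostureSeries:
    """Per-sample posture by maximum posterior cluster.

    Samples whose assigned-posture posterior (cluster posteriors pooled
    over the merge map) falls below the model's confidence threshold (0.6)
    are labeled ``unknown`` — high-motion
    segments land far from every orientation cluster and fail this gate.
    A 5 s median filter removes single-sample label flicker.
    """
    xyz = _normalize_gravity(_stack_xyz(accel_x, accel_y, accel_z))
    post = _posteriors(model, xyz)
    cluster = np.argmax(post, axis=1)
    # Confidence is the posterior of the assigned *posture*: clusters merged
    # to the same posture pool their posterior mass, so a posture covered by
    # two overlapping clusters is not spuriously low-confidence.
    posture_post = np.zeros((post.shape[0], len(POSTURES)))
    for c, name in enumerate(model.cluster_to_posture):
        posture_post[:, POSTURES.index(name)] += post[:, c]
    conf = posture_post[
        np.arange(post.shape[0]),
        np.array([POSTURES.index(model.cluster_to_posture[c]) for c in cluster]),
    ]

    # motion gate: high magnitude variance also maps to unknown, since a
    # sample mid-movement may still sit near a cluster by chance
    still = _motion_mask(xyz, accel_x.rate_hz)

    codes = np.array(
        [POSTURES.index(model.cluster_to_posture[c]) for c in cluster], dtype=int
    )
    n_med = max(int(round(median_filter_s * accel_x.rate_hz)), 1)
    if n_med % 2 == 0:
        n_med += 1
    if n_med >= 3 and codes.size >= n_med:
        codes = ndimage.median_filter(codes, size=n_med, mode="nearest")

    labels = np.array([POSTURES[c] for c in codes], dtype=object)
    unknown = (conf < model.confidence_threshold) | ~still
    labels[unknown] = "unknown"
    times = accel_x.t0_ms + np.arange(labels.size) * accel_x.dt_ms
    return PostureSeries(times_ms=times, labels=labels, confidence=conf)


def posture_vital_summary(
    postures: PostureSeries,
    vitals: list[VitalSeries],
    min_duration_s: float = 60.0,
    hist_bins: int = 30,
) -> pd.DataFrame:
    """Per-posture vital-sign distributions.

    Each vital sample is assigned the posture label nearest in time.
    Postures observed for less than ``min_duration_s`` are excluded.
    Returns one row per (posture, vital) with n, mean, SD, and histogram
    (bin edges + counts).
    """
    if postures.n == 0 or not vitals:
        return pd.DataFrame(
            columns=["posture", "vital", "n", "mean", "sd", "hist_edges", "hist_counts"]
        )
    dt_s = np.median(np.diff(postures.times_ms)) / 1000.0 if postures.n > 1 else 0.0
    dwell = {
        p: float((postures.labels == p).sum() * dt_s) for p in POSTURES
    }
    keep = {p for p, d in dwell.items() if d >= min_duration_s}

    rows = []
    for vs in vitals:
        finite = np.isfinite(vs.values)
        if not finite.any():
            continue
        t, v = vs.times_ms[finite], vs.values[finite]
        idx = np.clip(
            np.searchsorted(postures.times_ms, t), 0, postures.n - 1
        )
        # nearest, not insertion, point
        left = np.clip(idx - 1, 0, postures.n - 1)
        use_left = np.abs(postures.times_ms[left] - t) < np.abs(postures.times_ms[idx] - t)
        idx = np.where(use_left, left, idx)
        lab = postures.labels[idx]
        for p in sorted(keep):
            sel = lab == p
            if not sel.any():
                continue
            counts, edges = np.histogram(v[sel], bins=hist_bins)
            rows.append(
                {
                    "posture": p,
                    "vital": vs.vital,
                    "n": int(sel.sum()),
                    "mean": float(np.mean(v[sel])),
                    "sd": float(np.std(v[sel], ddof=1)) if sel.sum() > 1 else 0.0,
                    "hist_edges": edges.tolist(),
                    "hist_counts": counts.tolist(),
                }
            )
    return pd.DataFrame(rows)
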