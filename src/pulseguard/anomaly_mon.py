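"""Model-of-normality (MoN) anomaly detection with working-point thresholds.

A MoN is the arithmetic mean of the feature embeddings of N anomaly-free
samples.  A test sample is embedded, scored by Euclidean distance to the
MoN, and flagged as an anomaly when the score strictly exceeds a decision
threshold.  The threshold is set at one of six working points computed
from two calibration score vectors:

======  =========================
 rule    value
======  =========================
 T1      max(K1)
 T2      max(K1) - std(K1)
 T3      mean(K1) + std(K1)
 T4      max(K2)
 T5      max(K2) - std(K2)
 T6      mean(K2) + std(K2)
======  =========================

where K1 holds the scores of held-out normal calibration samples under
*max-pooled* embeddings and K2 the same under *mean-pooled* embeddings
(``std`` is the population standard deviation).  The embedding extractor
is any callable mapping an input to a feature vector or a 2-D feature map
(maps are pooled over their trailing axis to produce the two variants; a
plain vector serves as both).  A seeded random-projection encoder is
bundled as the default extractor so the detector runs without pretrained
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import h5py
import numpy as np

from .errors import CalibrationError, ConfigurationError, ShapeError

__all__ = [
    "FeatureVector",
    "MoNModel",
    "ThresholdSpec",
    "Decision",
    "RandomProjectionEncoder",
    "build_mon",
    "anomaly_score",
    "compute_threshold",
    "classify",
    "detect",
    "save_mon",
    "load_mon",
]

RULES = ("T1", "T2", "T3", "T4", "T5", "T6")


@dataclass
class FeatureVector:
    """A fixed-dimension embedding with the id of the sample it came from."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0 or not np.all(np.isfinite(self.values)):
            raise ShapeError("feature values must be non-empty and finite")


@dataclass
class MoNModel:
    """The normality embedding: mean of N normal feature vectors."""

    mon: np.ndarray
    n_normals: int
    class_label: str = "normal"

    def __post_init__(self):
        self.mon = np.asarray(self.mon, dtype=float)
        if self.n_normals < 1:
            raise ConfigurationError("n_normals must be >= 1")


@dataclass
class ThresholdSpec:
    """A working-point threshold with its provenance.

    ``value`` is recomputable from the stored calibration vectors via the
    rule's formula.
    """

    rule: str
    value: float
    K1: np.ndarray = field(default_factory=lambda: np.array([]))
    K2: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class Decision:
    """One classification outcome with full score/threshold provenance."""

    label: str
    score: float
    rule: str
    threshold: float
    n_normals: int
    source_id: str = ""


def _as_values(v):
    return v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)


def build_mon(normals: Sequence, class_label: str = "normal") -> MoNModel:
    """Elementwise arithmetic mean of N normal embeddings.

    The embeddings used here are, by contract, excluded from any
    evaluation set.
    """
    vectors = [_as_values(v) for v in normals]
    if len(vectors) == 0:
        raise CalibrationError("build_mon requires at least one normal vector")
    d = vectors[0].shape
    for i, v in enumerate(vectors):
        if v.shape != d:
            raise ShapeError(
                f"normal vector {i} has dimension {v.shape}, expected {d}")
    return MoNModel(mon=np.mean(vectors, axis=0), n_normals=len(vectors),
                    class_label=class_label)


def anomaly_score(mon: MoNModel, test) -> float:
    """Euclidean distance between the MoN and a test embedding."""
    t = _as_values(test)
    if t.shape != mon.mon.shape:
        raise ShapeError(
            f"test dimension {t.shape} does not match MoN dimension "
            f"{mon.mon.shape}")
    return float(np.sqrt(np.sum((mon.mon - t) ** 2)))


def compute_threshold(K1, K2, rule: str) -> ThresholdSpec:
    """Working-point threshold from the two calibration score vectors.

    ``std`` is the population standard deviation (divide by n).
    """
    if rule not in RULES:
        raise ConfigurationError(f"rule must be one of {RULES}, got '{rule}'")
    K1 = np.asarray(K1, dtype=float).ravel()
    K2 = np.asarray(K2, dtype=float).ravel()
    source = K1 if rule in ("T1", "T2", "T3") else K2
    if source.size == 0:
        raise CalibrationError(
            f"rule {rule} references an empty calibration score vector")
    if rule in ("T1", "T4"):
        value = source.max()
    elif rule in ("T2", "T5"):
        value = source.max() - source.std()
    else:  # T3, T6
        value = source.mean() + source.std()
    return ThresholdSpec(rule=rule, value=float(value), K1=K1, K2=K2)


def classify(score: float, threshold: ThresholdSpec) -> str:
    """'anomaly' iff the score strictly exceeds the threshold value."""
    return "anomaly" if score > threshold.value else "normal"


class RandomProjectionEncoder:
    """Seeded two-layer random-projection feature extractor.

    Maps a flattened input to a (n_channels, map_len) feature map by
    ``tanh(W2 relu(W1 x))``; weights are fixed at construction, never
    trained.  Serves as the bundled default embedding so the detector is
    exercisable without pretrained networks.
    """

    def __init__(self, input_dim: int, n_channels: int = 8, map_len: int = 16,
                 seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        hidden = n_channels * map_len
        self.W1 = rng.standard_normal((hidden, input_dim)) / np.sqrt(input_dim)
        self.W2 = rng.standard_normal((hidden, hidden)) / np.sqrt(hidden)
        self.n_channels, self.map_len = n_channels, map_len

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        h = np.maximum(self.W1 @ x, 0.0)
        return np.tanh(self.W2 @ h).reshape(self.n_channels, self.map_len)


def _pooled(feature_map: np.ndarray):
    """(max-pooled, mean-pooled) embeddings of an extractor output."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim == 1:
        return fm, fm
    return fm.max(axis=-1), fm.mean(axis=-1)


def detect(extractor: Callable, normals: Sequence, test, rule: str = "T3",
           n_mon: Optional[int] = None, source_id: str = "") -> Decision:
    """End-to-end detection: MoN build, calibration, scoring, decision.

    The first ``n_mon`` normals (default: half, at least one) build the
    MoN; the remaining normals form the held-out calibration split whose
    scores under max- and mean-pooled embeddings give K1 and K2.  The test
    sample is scored with the pooling variant matching the chosen rule.
    """
    normals = list(normals)
    if len(normals) < 2:
        raise CalibrationError(
            "detect needs >= 2 normals: one to build the MoN and one to "
            "calibrate the threshold")
    if n_mon is None:
        n_mon = max(1, len(normals) // 2)
    if not 1 <= n_mon < len(normals):
        raise CalibrationError(
            f"n_mon={n_mon} leaves an empty MoN or calibration split")
    maps = [_pooled(extractor(x)) for x in normals]
    mon_max = build_mon([m[0] for m in maps[:n_mon]])
    mon_mean = build_mon([m[1] for m in maps[:n_mon]])
    K1 = np.array([anomaly_score(mon_max, m[0]) for m in maps[n_mon:]])
    K2 = np.array([anomaly_score(mon_mean, m[1]) for m in maps[n_mon:]])
    threshold = compute_threshold(K1, K2, rule)
    t_max, t_mean = _pooled(extractor(test))
    if rule in ("T1", "T2", "T3"):
        score = anomaly_score(mon_max, t_max)
    else:
        score = anomaly_score(mon_mean, t_mean)
    return Decision(label=classify(score, threshold), score=score, rule=rule,
                    threshold=threshold.value, n_normals=n_mon,
                    source_id=source_id)


def save_mon(mon: MoNModel, path, group: str = "mon") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("mon", data=mon.mon)
        g.attrs["n_normals"] = mon.n_normals
        g.attrs["class_label"] = mon.class_label


def load_mon(path, group: str = "mon") -> MoNModel:
    with h5py.File(path, "r") as f:
        g = f[group]
        return MoNModel(mon=g["mon"][()], n_normals=int(g.attrs["n_normals"]),
                        class_label=str(g.attrs["class_label"]))
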