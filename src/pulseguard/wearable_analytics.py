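"""Descriptive heart-rate analytics for wearable CSV exports.

Covers the three standard views of an exported heart-rate stream: time
spent per intensity zone, distribution statistics with Tukey-fence outlier
flagging, and Pearson correlation matrices across physiological channels.

Zone boundaries are device-specific; the defaults follow the conventional
percentage-of-maximum-heart-rate bands ("Out of Range" below 50%, "Fat
Burn" 50-69%, "Cardio" 70-84%, "Peak" 85% and above) and are fully
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, InsufficientDataError,
                     UndefinedCorrelationError)

__all__ = [
    "HeartRateSeries",
    "ZoneDefinition",
    "default_zones",
    "zone_distribution",
    "summary_stats",
    "correlation_matrix",
    "read_heart_rate_csv",
]

ZONE_LABELS = ("Out of Range", "Fat Burn", "Cardio", "Peak")


@dataclass
class HeartRateSeries:
    """Timestamped beats-per-minute readings for one subject.

    ``timestamps`` are seconds (any monotone numeric clock); pandas
    datetimes are converted on construction.
    """

    timestamps: np.ndarray
    bpm: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        ts = pd.Series(self.timestamps)
        if np.issubdtype(ts.dtype, np.datetime64):
            ts = (ts - ts.iloc[0]).dt.total_seconds()
        self.timestamps = ts.to_numpy(dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if len(self.timestamps) != len(self.bpm):
            raise ConfigurationError("timestamps and bpm must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if np.any(self.bpm <= 0):
            raise ConfigurationError("bpm values must be positive")


@dataclass
class ZoneDefinition:
    """Ordered zone labels with bpm boundaries covering (0, inf).

    ``bounds`` holds the inner boundaries: zone i spans
    [bounds[i-1], bounds[i]) with implicit 0 and +inf at the ends.
    """

    labels: Tuple[str, ...] = ZONE_LABELS
    bounds: Tuple[float, ...] = (95.0, 133.0, 161.5)

    def __post_init__(self):
        if len(self.bounds) != len(self.labels) - 1:
            raise ConfigurationError(
                "need exactly one fewer boundary than zone labels")
        if np.any(np.diff(self.bounds) <= 0):
            raise ConfigurationError("zone boundaries must be increasing")

    def zone_of(self, bpm) -> np.ndarray:
        """Index of the zone containing each bpm value."""
        return np.searchsorted(self.bounds, np.asarray(bpm, dtype=float),
                               side="right")


def default_zones(max_hr: float = 190.0) -> ZoneDefinition:
    """Conventional percentage-of-max-HR bands (50 / 70 / 85%)."""
    return ZoneDefinition(bounds=(0.50 * max_hr, 0.70 * max_hr, 0.85 * max_hr))


def zone_distribution(series: HeartRateSeries,
                      zones: ZoneDefinition = None) -> Dict[str, float]:
    """Minutes spent per zone; conserves the total series duration.

    Each inter-sample interval is attributed to the zone of its leading
    sample, so irregular sampling is handled naturally.
    """
    if zones is None:
        zones = default_zones()
    if len(series.bpm) < 2:
        raise InsufficientDataError(
            "zone_distribution needs >= 2 samples to form an interval")
    intervals_min = np.diff(series.timestamps) / 60.0
    zone_idx = zones.zone_of(series.bpm[:-1])
    minutes = {label: 0.0 for label in zones.labels}
    for label_i, dt in zip(zone_idx, intervals_min):
        minutes[zones.labels[label_i]] += dt
    return minutes


def summary_stats(series: HeartRateSeries) -> dict:
    """Median, quartiles, IQR and Tukey-fence outliers of the bpm values.

    Quantiles use linear interpolation; outliers are values outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR].
    """
    bpm = series.bpm
    if len(bpm) < 4:
        raise InsufficientDataError(
            "summary_stats needs >= 4 samples for quartiles")
    q1, med, q3 = np.percentile(bpm, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = np.sort(bpm[(bpm < lo) | (bpm > hi)])
    return {"median": float(med), "Q1": float(q1), "Q3": float(q3),
            "IQR": float(iqr), "outliers": outliers,
            "fences": (float(lo), float(hi))}


def correlation_matrix(channels) -> pd.DataFrame:
    """Pearson correlation matrix of equally long named channels.

    ``channels`` is a mapping name -> sequence or a DataFrame.  Constant
    channels make the correlation undefined and raise, naming the channel.
    """
    frame = pd.DataFrame(dict(channels)) if not isinstance(channels, pd.DataFrame) \
        else channels.copy()
    if len(frame) < 3:
        raise InsufficientDataError(
            "correlation_matrix needs >= 3 samples per channel")
    for name in frame.columns:
        if np.ptp(frame[name].to_numpy(dtype=float)) == 0:
            raise UndefinedCorrelationError(
                f"channel '{name}' is constant; correlation undefined")
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=frame.columns, columns=frame.columns)


_TIME_NAMES = ("timestamp", "time", "datetime", "date")
_VALUE_NAMES = ("bpm", "value", "heart_rate", "heartrate", "hr")


def read_heart_rate_csv(path, subject_id: str = "") -> HeartRateSeries:
    """Read a wearable heart-rate CSV export.

    Tolerant of column naming: the time column is the first one named like
    timestamp/time/datetime, the value column the first named like
    bpm/value/heart_rate.  Non-numeric summary rows (e.g. zone label /
    minutes pairs appended below the samples) are dropped.
    """
    frame = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in frame.columns}
    t_col = next((cols[n] for n in _TIME_NAMES if n in cols), None)
    v_col = next((cols[n] for n in _VALUE_NAMES if n in cols), None)
    if t_col is None or v_col is None:
        raise ConfigurationError(
            f"could not locate timestamp/value columns in {list(frame.columns)}")
    values = pd.to_numeric(frame[v_col], errors="coerce")
    keep = values.notna()
    # numeric clocks are taken as seconds; otherwise parse as datetimes
    timestamps = pd.to_numeric(frame.loc[keep, t_col], errors="coerce")
    if not timestamps.notna().all():
        timestamps = pd.to_datetime(frame.loc[keep, t_col], errors="coerce")
    return HeartRateSeries(timestamps=timestamps.to_numpy(),
                           bpm=values[keep].to_numpy(),
                           subject_id=subject_id)
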