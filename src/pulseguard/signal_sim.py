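"""Seeded synthetic cardiovascular records with known SBP/DBP ground truth.

The simulator produces, per subject, a synchronized triple of waveforms at a
fixed sampling rate:

* **ABP** — a quasi-periodic arterial-pressure trace built from a per-beat
  template (systolic Gaussian peak plus a dicrotic bump on a diastolic
  baseline), rescaled per beat so the sampled maximum equals that beat's
  drawn SBP and the minimum its DBP.
* **PPG** — the ABP smoothed with a 50 ms moving average, min-max normalized
  over the record, plus additive Gaussian noise.  This preserves the
  physiological ABP-to-PPG morphology coupling without a hemodynamic model.
* **ECG** — an R-peak impulse train with one narrow peak per beat, placed a
  pulse-transit lag before the beat onset; the lag shrinks monotonically
  with the beat's mean arterial pressure.

A single dial, ``coupling_strength`` in [0, 1], controls how strongly the
waveform *morphology* (systolic peak width, dicrotic bump amplitude and
position, R-peak lag) encodes the underlying blood pressure.  At 0 the
normalized waveforms carry no BP information at all; at 1 the encoding is a
clean monotone map that a regressor can learn.

Everything is deterministic given ``(seed, subject_index)``; per-subject
streams are derived by seed-sequence spawning, so records are independent of
generation order.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ConfigurationError, InsufficientBeatsError

__all__ = [
    "SimConfig",
    "SignalRecord",
    "WindowedDataset",
    "simulate_record",
    "extract_sbp_dbp",
    "make_dataset",
    "write_record_csv",
    "read_record_csv",
    "write_record_hdf5",
    "read_record_hdf5",
]


@dataclass
class SimConfig:
    """Study conditions of a synthetic cohort.

    Defaults are the desk-scale benchmark conditions used throughout the
    package: 12 subjects, 60 s records at 125 Hz, full morphology coupling,
    noise scale 0.05.
    """

    n_subjects: int = 12
    duration_s: float = 60.0
    fs: float = 125.0
    hr_range: Tuple[float, float] = (55.0, 95.0)
    sbp_range: Tuple[float, float] = (100.0, 160.0)
    dbp_range: Tuple[float, float] = (60.0, 90.0)
    noise_sd: float = 0.05
    coupling_strength: float = 1.0
    seed: int = 7

    def validate(self) -> List[str]:
        v = []
        if not self.n_subjects >= 1:
            v.append(f"n_subjects must be a positive integer, got {self.n_subjects}")
        if not self.duration_s > 0:
            v.append(f"duration_s must be > 0, got {self.duration_s}")
        if not self.fs > 0:
            v.append(f"fs must be > 0, got {self.fs}")
        if not self.hr_range[0] <= self.hr_range[1] or self.hr_range[0] <= 0:
            v.append(f"hr_range must be an increasing positive pair, got {self.hr_range}")
        if not self.sbp_range[0] <= self.sbp_range[1]:
            v.append(f"sbp_range must be increasing, got {self.sbp_range}")
        if not self.dbp_range[0] <= self.dbp_range[1]:
            v.append(f"dbp_range must be increasing, got {self.dbp_range}")
        if not self.sbp_range[0] > self.dbp_range[1]:
            v.append(
                "sbp_range min must exceed dbp_range max (systolic always "
                f"above diastolic), got sbp_range={self.sbp_range} "
                f"dbp_range={self.dbp_range}")
        if not self.noise_sd >= 0:
            v.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.coupling_strength <= 1.0:
            v.append(f"coupling_strength must lie in [0, 1], got {self.coupling_strength}")
        return v

    def __post_init__(self):
        violations = self.validate()
        if violations:
            raise ConfigurationError(violations)


@dataclass
class SignalRecord:
    """One subject's synchronized PPG/ECG/ABP traces with per-beat labels.

    ``beat_onsets[k]`` is the sample index of beat k's diastolic foot; the
    beat occupies ``[beat_onsets[k], beat_onsets[k] + beat length)`` and
    carries labels ``sbp_per_beat[k]`` / ``dbp_per_beat[k]``.
    """

    subject_id: str
    fs: float
    ppg: np.ndarray
    ecg: np.ndarray
    abp: np.ndarray
    beat_onsets: np.ndarray
    sbp_per_beat: np.ndarray
    dbp_per_beat: np.ndarray

    def __post_init__(self):
        for name in ("ppg", "ecg", "abp", "sbp_per_beat", "dbp_per_beat"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.beat_onsets = np.asarray(self.beat_onsets, dtype=int)
        n = len(self.ppg)
        if not (len(self.ecg) == len(self.abp) == n):
            raise ConfigurationError("ppg, ecg, abp must have equal length")
        if np.any(np.diff(self.beat_onsets) <= 0):
            raise ConfigurationError("beat_onsets must be strictly increasing")
        if len(self.beat_onsets) and (self.beat_onsets[0] < 0
                                      or self.beat_onsets[-1] >= n):
            raise ConfigurationError("beat_onsets must lie within the record")
        if np.any(self.sbp_per_beat <= self.dbp_per_beat):
            raise ConfigurationError("sbp_per_beat must exceed dbp_per_beat")

    @property
    def n_samples(self) -> int:
        return len(self.ppg)

    @property
    def n_beats(self) -> int:
        return len(self.beat_onsets)


def _beat_shape(n: int, sbp_z: float, dbp_z: float,
                coupling: float) -> np.ndarray:
    """Normalized pulse shape on n samples: min exactly 0, max exactly 1.

    Morphology parameters drift monotonically with the (range-normalized)
    BP levels, scaled by the coupling strength: higher SBP narrows the
    systolic peak, higher DBP raises the dicrotic bump, higher MAP shifts
    the bump later in the cycle.
    """
    phase = np.arange(n) / n
    # higher SBP -> narrower systolic lobe (shorter ejection duty cycle)
    # and a later dicrotic bump; higher DBP -> taller bump
    sys_width = 0.17 - 0.12 * coupling * sbp_z
    dic_amp = 0.10 + 0.50 * coupling * dbp_z
    dic_pos = 0.45 + 0.25 * coupling * (sbp_z + dbp_z) / 2.0
    raw = (np.exp(-0.5 * ((phase - 0.22) / sys_width) ** 2)
           + dic_amp * np.exp(-0.5 * ((phase - dic_pos) / 0.07) ** 2))
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo)


def simulate_record(config: SimConfig, subject_index: int) -> SignalRecord:
    """Generate one subject's record, deterministic in (seed, subject_index)."""
    if subject_index >= config.n_subjects or subject_index < 0:
        raise ConfigurationError(
            f"subject_index {subject_index} out of range for "
            f"n_subjects={config.n_subjects}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, int(subject_index)]))

    fs = config.fs
    n_samples = int(round(config.duration_s * fs))
    hr = rng.uniform(*config.hr_range)
    beat_len = max(2, int(round(fs * 60.0 / hr)))
    n_beats = n_samples // beat_len
    if n_beats < 1:
        raise ConfigurationError(
            "duration_s too short to contain a single beat at the drawn "
            "heart rate")
    onsets = np.arange(n_beats) * beat_len

    # Subject-level BP with small per-beat jitter, clipped to the ranges.
    s_lo, s_hi = config.sbp_range
    d_lo, d_hi = config.dbp_range
    sbp_subj = rng.uniform(s_lo, s_hi)
    dbp_subj = rng.uniform(d_lo, d_hi)
    n_total = n_beats + 1  # one extra beat to fill the trailing tail

    def drift(width):
        """Slow within-record BP wander plus small beat-to-beat jitter."""
        if width == 0:
            return np.zeros(n_total)
        walk = np.cumsum(rng.standard_normal(n_total))
        walk = uniform_filter1d(walk, size=max(3, n_total // 8), mode="nearest")
        sd = walk.std()
        slow = 0.06 * width * walk / sd if sd > 0 else np.zeros(n_total)
        return slow + 0.02 * width * rng.standard_normal(n_total)

    sbp = np.clip(sbp_subj + drift(s_hi - s_lo), s_lo, s_hi)
    dbp = np.clip(dbp_subj + drift(d_hi - d_lo), d_lo, d_hi)

    def norm(val, lo, hi):
        return 0.5 if hi == lo else (val - lo) / (hi - lo)

    abp = np.empty(n_total * beat_len)
    lags = np.empty(n_total, dtype=int)
    for k in range(n_total):
        mean_ap = dbp[k] + (sbp[k] - dbp[k]) / 3.0
        sbp_z = norm(sbp[k], s_lo, s_hi)
        dbp_z = norm(dbp[k], d_lo, d_hi)
        map_z = norm(mean_ap, d_lo + (s_lo - d_lo) / 3.0,
                     d_hi + (s_hi - d_hi) / 3.0)
        shape = _beat_shape(beat_len, sbp_z, dbp_z,
                            config.coupling_strength)
        abp[k * beat_len:(k + 1) * beat_len] = dbp[k] + (sbp[k] - dbp[k]) * shape
        # pulse-transit lag: 280 ms baseline, shrinking with systolic
        # pressure (the classic inverse PTT-BP relation)
        lags[k] = int(round(fs * (0.28 - 0.14 * config.coupling_strength
                                  * (0.7 * sbp_z + 0.3 * map_z))))
    abp = abp[:n_samples]

    # PPG: 50 ms moving average of ABP, min-max normalized, plus noise.
    kernel = max(1, int(round(0.05 * fs)))
    smooth = uniform_filter1d(abp, size=kernel, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    ppg = (smooth - lo) / (hi - lo) if hi > lo else np.zeros_like(smooth)
    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, size=n_samples)

    # ECG: one QRS-width R-peak a lag before each beat onset.
    ecg = np.zeros(n_samples)
    r_width = max(1.0, 0.028 * fs)
    t_idx = np.arange(n_samples)
    for k in range(n_total):
        r_pos = k * beat_len - lags[k]
        if r_pos < 0 or r_pos >= n_samples:
            continue
        lo_i = max(0, int(r_pos - 4 * r_width))
        hi_i = min(n_samples, int(r_pos + 4 * r_width) + 1)
        ecg[lo_i:hi_i] += np.exp(
            -0.5 * ((t_idx[lo_i:hi_i] - r_pos) / r_width) ** 2)
    if config.noise_sd > 0:
        ecg = ecg + rng.normal(0.0, config.noise_sd, size=n_samples)

    return SignalRecord(
        subject_id=f"S{subject_index:03d}",
        fs=fs, ppg=ppg, ecg=ecg, abp=abp,
        beat_onsets=onsets,
        sbp_per_beat=sbp[:n_beats],
        dbp_per_beat=dbp[:n_beats],
    )


def extract_sbp_dbp(abp, beat_onsets) -> Tuple[np.ndarray, np.ndarray]:
    """Per-beat systolic (max) and diastolic (min) pressure from a waveform.

    Beat k spans the half-open interval ``[onset_k, onset_{k+1})``; the
    trailing partial beat after the last onset is dropped, so the output has
    ``len(beat_onsets) - 1`` entries.
    """
    abp = np.asarray(abp, dtype=float)
    onsets = np.asarray(beat_onsets, dtype=int)
    if len(onsets) < 2:
        raise InsufficientBeatsError(
            "at least two beat onsets are required to delimit one complete "
            "beat interval")
    sbp = np.empty(len(onsets) - 1)
    dbp = np.empty(len(onsets) - 1)
    for k in range(len(onsets) - 1):
        seg = abp[onsets[k]:onsets[k + 1]]
        sbp[k] = seg.max()
        dbp[k] = seg.min()
    return sbp, dbp


@dataclass
class WindowedDataset:
    """Sliding windows over a cohort, with waveform and SBP/DBP targets.

    ``rel_onsets[i]`` holds beat-onset indices relative to window i's start
    (including the onset that closes the last complete beat), aligned with
    ``beat_sbp[i]`` / ``beat_dbp[i]``; ``sbp[i]`` / ``dbp[i]`` are the means
    of those per-beat labels.
    """

    fs: float
    window_s: float
    stride_s: float
    ppg: np.ndarray          # (n_windows, window_len)
    ecg: np.ndarray          # (n_windows, window_len)
    abp: np.ndarray          # (n_windows, window_len), mmHg
    sbp: np.ndarray          # (n_windows,), mmHg
    dbp: np.ndarray          # (n_windows,), mmHg
    subject_ids: np.ndarray  # (n_windows,), strings
    rel_onsets: list = field(default_factory=list)
    beat_sbp: list = field(default_factory=list)
    beat_dbp: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.ppg.shape[0]

    @property
    def window_len(self) -> int:
        return self.ppg.shape[1]

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def inputs(self, channels: str = "ppg") -> np.ndarray:
        """Stack the requested channels into an (n, C, L) array."""
        if channels == "ppg":
            return self.ppg[:, None, :]
        if channels == "ppg_ecg":
            return np.stack([self.ppg, self.ecg], axis=1)
        raise ConfigurationError(
            f"channels must be 'ppg' or 'ppg_ecg', got '{channels}'")

    def subset(self, mask) -> "WindowedDataset":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else mask
        return WindowedDataset(
            fs=self.fs, window_s=self.window_s, stride_s=self.stride_s,
            ppg=self.ppg[idx], ecg=self.ecg[idx], abp=self.abp[idx],
            sbp=self.sbp[idx], dbp=self.dbp[idx],
            subject_ids=self.subject_ids[idx],
            rel_onsets=[self.rel_onsets[i] for i in idx],
            beat_sbp=[self.beat_sbp[i] for i in idx],
            beat_dbp=[self.beat_dbp[i] for i in idx])


def make_dataset(config: SimConfig, window_s: float = 5.0,
                 stride_s: float = 5.0) -> WindowedDataset:
    """Simulate the whole cohort and cut it into sliding windows.

    Each window carries the PPG/ECG inputs, the ABP segment, the onsets and
    SBP/DBP labels of every beat fully contained in it, and the subject id
    for leave-one-subject-out grouping.  Windows are cut on the stride grid
    regardless of beat phase, so window starts fall at arbitrary points of
    the cardiac cycle.  Windows containing no complete beat are skipped
    with a warning.
    """
    if stride_s <= 0:
        raise ConfigurationError(f"stride_s must be > 0, got {stride_s}")
    if window_s > config.duration_s:
        raise ConfigurationError(
            f"window_s={window_s} exceeds duration_s={config.duration_s}")
    win = int(round(window_s * config.fs))
    stride = int(round(stride_s * config.fs))
    ppg_w, ecg_w, abp_w, sbp_w, dbp_w, sid_w = [], [], [], [], [], []
    rel_onsets, beat_sbp, beat_dbp = [], [], []
    for s in range(config.n_subjects):
        rec = simulate_record(config, s)
        beat_len = (rec.beat_onsets[1] - rec.beat_onsets[0]
                    if rec.n_beats > 1 else rec.n_samples)
        for start in range(0, rec.n_samples - win + 1, stride):
            stop = start + win
            inside = np.flatnonzero(
                (rec.beat_onsets >= start) & (rec.beat_onsets + beat_len <= stop))
            if len(inside) == 0:
                warnings.warn(
                    f"window at {start / config.fs:.1f}s of {rec.subject_id} "
                    "contains no complete beat; skipped")
                continue
            ppg_w.append(rec.ppg[start:stop])
            ecg_w.append(rec.ecg[start:stop])
            abp_w.append(rec.abp[start:stop])
            sbp_w.append(rec.sbp_per_beat[inside].mean())
            dbp_w.append(rec.dbp_per_beat[inside].mean())
            sid_w.append(rec.subject_id)
            # onsets delimiting the contained beats, window-relative
            bounds = np.append(rec.beat_onsets[inside],
                               rec.beat_onsets[inside[-1]] + beat_len) - start
            rel_onsets.append(bounds.astype(int))
            beat_sbp.append(rec.sbp_per_beat[inside].copy())
            beat_dbp.append(rec.dbp_per_beat[inside].copy())
    return WindowedDataset(
        fs=config.fs, window_s=window_s, stride_s=stride_s,
        ppg=np.asarray(ppg_w), ecg=np.asarray(ecg_w), abp=np.asarray(abp_w),
        sbp=np.asarray(sbp_w), dbp=np.asarray(dbp_w),
        subject_ids=np.asarray(sid_w),
        rel_onsets=rel_onsets, beat_sbp=beat_sbp, beat_dbp=beat_dbp)


# ---------------------------------------------------------------------------
# Record IO
# ---------------------------------------------------------------------------

def write_record_csv(record: SignalRecord, path) -> None:
    """CSV with columns t, ppg, ecg, abp; beat metadata in '#' header lines."""
    meta = {
        "subject_id": record.subject_id,
        "fs": record.fs,
        "beat_onsets": record.beat_onsets.tolist(),
        "sbp_per_beat": record.sbp_per_beat.tolist(),
        "dbp_per_beat": record.dbp_per_beat.tolist(),
    }
    t = np.arange(record.n_samples) / record.fs
    frame = pd.DataFrame({"t": t, "ppg": record.ppg, "ecg": record.ecg,
                          "abp": record.abp})
    buf = io.StringIO()
    buf.write("# pulseguard-record " + json.dumps(meta) + "\n")
    frame.to_csv(buf, index=False, float_format="%.10g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_record_csv(path) -> SignalRecord:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# pulseguard-record "):
        raise ConfigurationError(f"{path} is not a pulseguard record CSV")
    meta = json.loads(header[len("# pulseguard-record "):])
    frame = pd.read_csv(path, comment="#")
    return SignalRecord(
        subject_id=meta["subject_id"], fs=meta["fs"],
        ppg=frame["ppg"].to_numpy(), ecg=frame["ecg"].to_numpy(),
        abp=frame["abp"].to_numpy(),
        beat_onsets=np.asarray(meta["beat_onsets"]),
        sbp_per_beat=np.asarray(meta["sbp_per_beat"]),
        dbp_per_beat=np.asarray(meta["dbp_per_beat"]))


def write_record_hdf5(record: SignalRecord, path, group: str = None) -> None:
    name = group or record.subject_id
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        for key in ("ppg", "ecg", "abp", "beat_onsets", "sbp_per_beat",
                    "dbp_per_beat"):
            g.create_dataset(key, data=getattr(record, key))
        g.attrs["fs"] = record.fs
        g.attrs["subject_id"] = record.subject_id


def read_record_hdf5(path, group: str) -> SignalRecord:
    with h5py.File(path, "r") as f:
        g = f[group]
        return SignalRecord(
            subject_id=str(g.attrs["subject_id"]), fs=float(g.attrs["fs"]),
            ppg=g["ppg"][()], ecg=g["ecg"][()], abp=g["abp"][()],
            beat_onsets=g["beat_onsets"][()],
            sbp_per_beat=g["sbp_per_beat"][()],
            dbp_per_beat=g["dbp_per_beat"][()])
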