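"""Training loop, MAE/RMSE metrics and leave-one-subject-out evaluation.

The evaluation protocol holds out one subject per fold, trains on all the
others and scores the held-out subject's windows; aggregate metrics are the
sample-count-weighted mean of the fold metrics.  Two prediction modes are
scored:

* **direct** — the model's two head outputs against the per-window SBP/DBP
  labels (window-level waveform errors are not defined in this mode and
  are reported as absent);
* **entire** — the predicted ABP waveform against the true one (MAE/RMSE
  in mmHg), and additionally per-beat SBP/DBP derived from the predicted
  waveform via :func:`pulseguard.signal_sim.extract_sbp_dbp`, scored
  against the true per-beat labels.

All randomness (initialization, shuffling, dropout, validation split) is
keyed to ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from . import autodiff as ad
from .architectures import Model, ModelSpec, build_model
from .errors import ConfigurationError, DivergenceError, ShapeError
from .signal_sim import WindowedDataset, extract_sbp_dbp

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "FoldResult",
    "EvalReport",
    "mae",
    "rmse",
    "train",
    "loo_evaluate",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _paired(pred, truth):
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size == 0 or p.size != t.size:
        raise ShapeError(
            f"pred and truth must have equal nonzero lengths, got "
            f"{p.size} and {t.size}")
    return p, t


def mae(pred, truth) -> float:
    """Mean absolute error, in the units of the inputs (mmHg here)."""
    p, t = _paired(pred, truth)
    return float(np.mean(np.abs(p - t)))


def rmse(pred, truth) -> float:
    """Root-mean-square error; always >= mae on the same pair."""
    p, t = _paired(pred, truth)
    return float(np.sqrt(np.mean((p - t) ** 2)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 32
    learning_rate: float = 3e-3
    lr_decay: float = 0.97  # per-epoch multiplicative decay
    loss: str = "mse"
    seed: int = 0
    early_stop_patience: int = 15
    val_fraction: float = 0.1

    def __post_init__(self):
        v = []
        if self.epochs < 0:
            v.append("epochs must be >= 0")
        if self.batch_size < 1:
            v.append("batch_size must be positive")
        if self.learning_rate < 0:
            v.append("learning_rate must be >= 0")
        if not 0.0 < self.lr_decay <= 1.0:
            v.append("lr_decay must lie in (0, 1]")
        if self.loss not in ("mse", "cross_entropy"):
            v.append(f"loss must be 'mse' or 'cross_entropy', got '{self.loss}'")
        if self.early_stop_patience < 1:
            v.append("early_stop_patience must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            v.append("val_fraction must lie in [0, 1)")
        if v:
            raise ConfigurationError(v)


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1


def _targets_for(model: Model, dataset: WindowedDataset):
    head = model.spec.head
    if head == "direct_sbp_dbp":
        return np.column_stack([dataset.sbp, dataset.dbp])
    if head == "entire_waveform":
        return dataset.abp
    raise ConfigurationError(
        "train on a WindowedDataset supports regression heads; pass (X, y) "
        "arrays for stage_classifier")


def train(model: Model, dataset, config: TrainConfig) -> TrainHistory:
    """Fit ``model`` in place; returns the per-epoch loss history.

    ``dataset`` is either a :class:`WindowedDataset` (inputs and targets
    are derived from the model's channel and head configuration) or an
    ``(X, y)`` tuple with ``X`` of shape (n, C, L).  Targets are z-scored
    with training-set statistics (stored on the model, which de-normalizes
    its predictions); a 10% validation split drives early stopping.
    """
    if isinstance(dataset, WindowedDataset):
        x = dataset.inputs(model.spec.channels)
        y = _targets_for(model, dataset)
    else:
        x, y = dataset
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
    if len(x) == 0:
        raise ConfigurationError("training dataset is empty")
    classification = model.spec.head == "stage_classifier"
    if x.ndim == 2:
        x = x[:, None, :]

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, 17]))
    history = TrainHistory()
    if config.epochs == 0:
        return history

    # normalization statistics from the training portion
    model.x_mean = x.mean(axis=(0, 2))
    model.x_std = x.std(axis=(0, 2))
    model.x_std[model.x_std == 0] = 1.0
    xn = (x - model.x_mean[None, :, None]) / model.x_std[None, :, None]
    if classification:
        yn = np.asarray(y, dtype=int)
    else:
        y = np.asarray(y, dtype=float)
        y2 = y if y.ndim == 2 else y[:, None]
        model.y_mean = y2.mean(axis=0) if model.spec.head == "direct_sbp_dbp" \
            else np.full(model.y_mean.shape, y2.mean())
        scale = y2.std(axis=0) if model.spec.head == "direct_sbp_dbp" \
            else np.full(model.y_std.shape, y2.std())
        scale[scale == 0] = 1.0
        model.y_std = scale
        yn = (y2 - model.y_mean) / model.y_std
        if yn.shape[1] != model.y_mean.shape[0]:
            raise ShapeError("target width does not match the model head")

    n = len(xn)
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]

    opt = ad.Adam(model.parameters(), lr=config.learning_rate)
    best_val, best_state, patience = np.inf, None, 0
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay ** epoch
        order = rng.permutation(tr_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            xb = ad.Tensor(xn[batch])
            out = model.forward_tensor(xb, train=True, rng=rng)
            if classification:
                loss = ad.softmax_cross_entropy(out, yn[batch])
            else:
                loss = ad.mse_loss(out, yn[batch])
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.train_loss.append(epoch_loss / max(n_batches, 1))

        if len(val_idx):
            out = model.forward_tensor(ad.Tensor(xn[val_idx]))
            vloss = (ad.softmax_cross_entropy(out, yn[val_idx]) if classification
                     else ad.mse_loss(out, yn[val_idx]))
            vl = float(vloss.data)
        else:
            vl = history.train_loss[-1]
        history.val_loss.append(vl)
        if vl < best_val - 1e-12:
            best_val, best_state = vl, model.get_state()
            history.best_epoch = epoch
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_state is not None:
        model.set_state(best_state)
    return history


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    subject_id: str
    n_windows: int
    mae_s: float
    mae_d: float
    rmse_s: float
    rmse_d: float
    wave_mae: Optional[float] = None
    wave_rmse: Optional[float] = None


@dataclass
class EvalReport:
    """Per-fold and aggregate errors, mirroring the LOO result layout.

    Waveform-level MAE/RMSE exist only in ``entire`` mode; in ``direct``
    mode they are reported as absent (None).  Aggregates are sample-count
    weighted means of the fold metrics.
    """

    mode: str
    channels: str
    n_subjects: int
    folds: List[FoldResult] = field(default_factory=list)
    skipped_subjects: List[str] = field(default_factory=list)

    def _weighted(self, attr) -> Optional[float]:
        vals = [(getattr(f, attr), f.n_windows) for f in self.folds
                if getattr(f, attr) is not None]
        if not vals:
            return None
        w = np.array([v[1] for v in vals], dtype=float)
        x = np.array([v[0] for v in vals], dtype=float)
        return float(np.sum(w * x) / np.sum(w))

    @property
    def mae_s(self):
        return self._weighted("mae_s")

    @property
    def mae_d(self):
        return self._weighted("mae_d")

    @property
    def rmse_s(self):
        return self._weighted("rmse_s")

    @property
    def rmse_d(self):
        return self._weighted("rmse_d")

    @property
    def wave_mae(self):
        return self._weighted("wave_mae")

    @property
    def wave_rmse(self):
        return self._weighted("wave_rmse")

    def to_frame(self) -> pd.DataFrame:
        """One row per fold plus an aggregate row, LOO-table column names."""
        rows = []
        for f in self.folds + [None]:
            if f is None:
                rows.append({
                    "Tested set": "aggregate", "RMSE": self.wave_rmse,
                    "MAE": self.wave_mae, "MAE D": self.mae_d,
                    "MAE S": self.mae_s, "RMSE D": self.rmse_d,
                    "RMSE S": self.rmse_s, "n windows": sum(
                        x.n_windows for x in self.folds)})
            else:
                rows.append({
                    "Tested set": f.subject_id, "RMSE": f.wave_rmse,
                    "MAE": f.wave_mae, "MAE D": f.mae_d, "MAE S": f.mae_s,
                    "RMSE D": f.rmse_d, "RMSE S": f.rmse_s,
                    "n windows": f.n_windows})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def clean(v):
            return None if v is None else float(v)

        return json.dumps({
            "mode": self.mode, "channels": self.channels,
            "n_subjects": self.n_subjects,
            "aggregate": {k: clean(getattr(self, k)) for k in (
                "wave_rmse", "wave_mae", "mae_d", "mae_s", "rmse_d",
                "rmse_s")},
            "folds": [vars(f) for f in self.folds],
            "skipped_subjects": self.skipped_subjects,
        }, indent=2)


def _mode_of(spec: ModelSpec) -> str:
    return "entire" if spec.head == "entire_waveform" else "direct"


def loo_evaluate(spec: ModelSpec, dataset: WindowedDataset,
                 config: TrainConfig) -> EvalReport:
    """Leave-one-subject-out evaluation of the network ``spec`` describes."""
    subjects = list(dataset.subjects())
    if len(subjects) < 2:
        raise ConfigurationError("loo_evaluate requires >= 2 subjects")
    mode = _mode_of(spec)
    report = EvalReport(mode=mode, channels=spec.channels,
                        n_subjects=len(subjects))
    for fold, subject in enumerate(subjects):
        test_mask = dataset.subject_ids == subject
        if not test_mask.any():
            warnings.warn(f"subject {subject} has no test windows; fold skipped")
            report.skipped_subjects.append(subject)
            continue
        train_set = dataset.subset(~test_mask)
        test_set = dataset.subset(test_mask)
        fold_seed = (int(config.seed) * 1009 + fold) & 0x7FFFFFFF
        model = build_model(replace(spec, seed=fold_seed))
        train(model, train_set, replace(config, seed=fold_seed))
        pred = model.forward(test_set.inputs(spec.channels))
        if mode == "direct":
            report.folds.append(FoldResult(
                subject_id=subject, n_windows=test_set.n_windows,
                mae_s=mae(pred[:, 0], test_set.sbp),
                mae_d=mae(pred[:, 1], test_set.dbp),
                rmse_s=rmse(pred[:, 0], test_set.sbp),
                rmse_d=rmse(pred[:, 1], test_set.dbp)))
        else:
            sbp_hat, dbp_hat, sbp_true, dbp_true = [], [], [], []
            for i in range(test_set.n_windows):
                s, d = extract_sbp_dbp(pred[i], test_set.rel_onsets[i])
                k = len(s)
                sbp_hat.append(s)
                dbp_hat.append(d)
                sbp_true.append(test_set.beat_sbp[i][:k])
                dbp_true.append(test_set.beat_dbp[i][:k])
            sbp_hat = np.concatenate(sbp_hat)
            dbp_hat = np.concatenate(dbp_hat)
            sbp_true = np.concatenate(sbp_true)
            dbp_true = np.concatenate(dbp_true)
            report.folds.append(FoldResult(
                subject_id=subject, n_windows=test_set.n_windows,
                mae_s=mae(sbp_hat, sbp_true), mae_d=mae(dbp_hat, dbp_true),
                rmse_s=rmse(sbp_hat, sbp_true),
                rmse_d=rmse(dbp_hat, dbp_true),
                wave_mae=mae(pred, test_set.abp),
                wave_rmse=rmse(pred, test_set.abp)))
    return report
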