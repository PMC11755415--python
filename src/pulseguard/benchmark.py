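"""The package's canonical desk-scale BP-prediction benchmark.

One fixed study: the default synthetic cohort (12 subjects, 60 s records at
125 Hz, full morphology coupling, noise 0.05) cut into 2.5 s windows on a
2.5 s stride, evaluated leave-one-subject-out.  The network under test is
the hybrid ResNet+LSTM at reduced width (6 convolutional channels, hidden
size 16, dropout 0.05), trained 80 epochs with Adam (lr 3e-3, 0.97/epoch
decay, batch 32).  Reference predictors: the least-squares linear baseline
on flattened windows and the training-mean predictor.

Everything here is a thin, named wrapper over the library so that scripts,
tests and notebooks measure exactly the same quantities.
"""

from __future__ import annotations

import numpy as np

from .architectures import ModelSpec, build_model, fit_linear_baseline
from .signal_sim import SimConfig, WindowedDataset, make_dataset
from .train_eval import EvalReport, TrainConfig, loo_evaluate, mae, train

__all__ = [
    "benchmark_dataset",
    "benchmark_model_spec",
    "benchmark_train_config",
    "loo_baseline_sbp_mae",
    "run_loo_benchmark",
    "validation_sbp_mae",
]

WINDOW_S = 2.5
STRIDE_S = 2.5


def benchmark_dataset(sim_config: SimConfig = None) -> WindowedDataset:
    """The benchmark cohort, windowed (defaults are the study conditions)."""
    return make_dataset(sim_config or SimConfig(), WINDOW_S, STRIDE_S)


def benchmark_model_spec(channels: str = "ppg", seed: int = 0,
                         window_len: int = None) -> ModelSpec:
    # width scales with the input channels: a PPG+ECG model is ~4x the
    # cost of its PPG twin, matching the family's cost-model convention
    if window_len is None:
        window_len = int(WINDOW_S * SimConfig().fs)
    return ModelSpec(family="resnet_lstm", channels=channels,
                     head="direct_sbp_dbp", hidden_size=16, conv_width=6,
                     dropout_rate=0.05, window_len=window_len,
                     scale_width_with_channels=True, seed=seed)


def benchmark_train_config(seed: int = 0) -> TrainConfig:
    # patience equals the epoch budget: the full schedule always runs and
    # the best-validation parameters are kept
    return TrainConfig(epochs=80, learning_rate=3e-3, lr_decay=0.97,
                       batch_size=32, early_stop_patience=80, seed=seed)


def run_loo_benchmark(dataset: WindowedDataset, channels: str = "ppg",
                      seed: int = 0) -> EvalReport:
    """Leave-one-subject-out evaluation of the benchmark ResNet+LSTM."""
    spec = benchmark_model_spec(channels, seed, dataset.window_len)
    return loo_evaluate(spec, dataset, benchmark_train_config(seed))


def loo_baseline_sbp_mae(dataset: WindowedDataset):
    """(linear-baseline, mean-predictor) aggregate SBP MAE under LOO."""
    lin_err, mean_err, weights = [], [], []
    for subject in dataset.subjects():
        held_out = dataset.subject_ids == subject
        tr, te = dataset.subset(~held_out), dataset.subset(held_out)
        baseline = fit_linear_baseline(
            tr.ppg, np.column_stack([tr.sbp, tr.dbp]))
        pred = baseline.predict(te.ppg)
        lin_err.append(mae(pred[:, 0], te.sbp))
        mean_err.append(mae(np.full(te.n_windows, tr.sbp.mean()), te.sbp))
        weights.append(te.n_windows)
    w = np.asarray(weights, dtype=float)
    return (float(np.sum(lin_err * w) / w.sum()),
            float(np.sum(mean_err * w) / w.sum()))


def validation_sbp_mae(dataset: WindowedDataset, channels: str,
                       seed: int) -> float:
    """SBP MAE on a held-out 10% window split after full-cohort training.

    The quick estimate used to compare input-channel configurations
    without a full LOO pass.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    n = dataset.n_windows
    perm = rng.permutation(n)
    n_val = max(1, n // 10)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    tr, val = dataset.subset(tr_idx), dataset.subset(val_idx)
    model = build_model(benchmark_model_spec(channels, seed,
                                             dataset.window_len))
    train(model, tr, benchmark_train_config(seed))
    pred = model.forward(val.inputs(channels))
    return mae(pred[:, 0], val.sbp)
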