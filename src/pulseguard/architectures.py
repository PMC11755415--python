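"""The five compared network families for cuffless BP estimation.

Families
--------
* ``fully_connected`` — flattened window through a stack of ReLU dense
  layers.
* ``lstm`` — the window, decimated by average pooling, fed to an LSTM.
* ``wavenet`` — a stack of dilated causal 1-D convolutions with the
  dilation doubling per layer (1, 2, 4, ...) and residual sums; a
  simplification without the gated tanh/sigmoid units of the original.
* ``wavenet_lstm`` — the WaveNet stack followed by an LSTM.
* ``resnet_lstm`` — the hybrid layout: five convolutional blocks holding
  (3, 3, 2, 2, 2) convolutions of kernel size 3 with ReLU and a residual
  skip per block, each block closed by a 2-wide max-pool and 25% dropout
  (12 convolutions and 5 pools in total), then one LSTM layer, one FC
  layer, and the selected head.

Heads: ``direct_sbp_dbp`` (two regressed values, affinely de-normalized
from z-scores using training-set statistics), ``entire_waveform`` (one
output per input sample) and ``stage_classifier`` (softmax over
hypertension stages).

All models are 1-D: the BP task is regression on signals, and the
classification head sits on the same 1-D encoder.  With
``scale_width_with_channels`` the internal representation width doubles
for PPG+ECG input, making such a model roughly four times the cost of its
PPG twin (the width enters the cost quadratically).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from . import autodiff as ad
from .errors import ConfigurationError, ShapeError
from .nn_core import softmax

__all__ = [
    "FAMILIES",
    "FAMILY_LABELS",
    "CHANNELS",
    "HEADS",
    "ModelSpec",
    "Model",
    "LinearBaseline",
    "build_model",
    "family_from_label",
    "fit_linear_baseline",
    "hypertension_stage",
    "save_model",
    "load_model",
]

FAMILIES = ("fully_connected", "lstm", "wavenet", "wavenet_lstm",
            "resnet_lstm")

# canonical result-table row labels for each family
FAMILY_LABELS = {
    "fully_connected": "Fully connected",
    "lstm": "Long Short-Term Memory",
    "wavenet": "WaveNet",
    "wavenet_lstm": "WaveNet + Long Short-Term Memory",
    "resnet_lstm": "ResNet + Long Short-Term Memory",
}


def family_from_label(label: str) -> str:
    """Resolve a family from its snake_case name or its table row label."""
    if label in FAMILIES:
        return label
    lowered = label.strip().lower()
    for family, pretty in FAMILY_LABELS.items():
        if lowered == pretty.lower():
            return family
    raise ConfigurationError(
        f"unknown model family '{label}'; expected one of {FAMILIES} or "
        f"{tuple(FAMILY_LABELS.values())}")
CHANNELS = ("ppg", "ppg_ecg")
HEADS = ("direct_sbp_dbp", "entire_waveform", "stage_classifier")

# conv-per-block allocation of the hybrid: 12 convolutions over 5 blocks
_RESNET_BLOCK_CONVS = (3, 3, 2, 2, 2)


@dataclass
class ModelSpec:
    """Declarative description of one network.

    ``hidden_size`` is the LSTM/dense width per input channel and
    ``conv_width`` the convolutional channel count per input channel (both
    are doubled for ``ppg_ecg`` input).  ``depth`` controls the dilated
    stack of the wavenet families and the dense stack of the fully
    connected family; the resnet_lstm layout is fixed.  ``lstm_decimation``
    is the average-pooling factor the plain lstm family applies before its
    recurrence.
    """

    family: str
    channels: str = "ppg"
    head: str = "direct_sbp_dbp"
    hidden_size: int = 16
    depth: int = 4
    kernel_size: int = 3
    dropout_rate: float = 0.25
    conv_width: int = 4
    window_len: int = 625
    n_classes: int = 4
    lstm_decimation: int = 5
    scale_width_with_channels: bool = False
    seed: int = 0

    def __post_init__(self):
        v = []
        if self.family not in FAMILIES:
            v.append(f"family must be one of {FAMILIES}, got '{self.family}'")
        if self.channels not in CHANNELS:
            v.append(f"channels must be one of {CHANNELS}, got '{self.channels}'")
        if self.head not in HEADS:
            v.append(f"head must be one of {HEADS}, got '{self.head}'")
        for name in ("hidden_size", "depth", "kernel_size", "conv_width",
                     "window_len", "lstm_decimation"):
            if getattr(self, name) < 1:
                v.append(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            v.append(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.head == "stage_classifier" and self.n_classes < 2:
            v.append("stage_classifier head requires n_classes >= 2")
        if v:
            raise ConfigurationError(v)

    @property
    def n_input_channels(self) -> int:
        return 2 if self.channels == "ppg_ecg" else 1


class Model:
    """A built, trainable network; construct through :func:`build_model`."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 91]))
        n_in = spec.n_input_channels
        scale = n_in if spec.scale_width_with_channels else 1
        self.width = spec.conv_width * scale
        self.hidden = spec.hidden_size * scale
        self._conv_layers = []
        self._pool_layers = []
        self._dropout_layers = []
        self._dense_layers = []
        self._lstm = None
        self._build(rng)
        self._build_head(rng)
        # normalization statistics, set by training
        self.x_mean = np.zeros(n_in)
        self.x_std = np.ones(n_in)
        self.y_mean = np.zeros(self._head_dim)
        self.y_std = np.ones(self._head_dim)

    # -- construction -----------------------------------------------------
    def _build(self, rng):
        spec = self.spec
        n_in, w, h, length = (spec.n_input_channels, self.width, self.hidden,
                              spec.window_len)
        fam = spec.family
        if fam == "fully_connected":
            dims = [n_in * length] + [h] * spec.depth
            for a, b in zip(dims[:-1], dims[1:]):
                self._dense_layers.append(ad.Dense(a, b, rng, activation="relu"))
            self._feature_dim = h
        elif fam == "lstm":
            self._decimate = ad.AvgDecimate1d(spec.lstm_decimation)
            self._lstm = ad.LSTMLayer(n_in, h, rng,
                                      seq_len=length // spec.lstm_decimation)
            self._feature_dim = h
        elif fam in ("wavenet", "wavenet_lstm"):
            c_in = n_in
            for i in range(spec.depth):
                self._conv_layers.append(ad.Conv1d(
                    c_in, w, spec.kernel_size, rng, dilation=2 ** i,
                    causal=True, length=length))
                c_in = w
            if fam == "wavenet_lstm":
                self._lstm = ad.LSTMLayer(w, h, rng, seq_len=length)
                self._feature_dim = h
            else:
                self._feature_dim = w
        elif fam == "resnet_lstm":
            c_in, cur_len = n_in, length
            for n_convs in _RESNET_BLOCK_CONVS:
                for _ in range(n_convs):
                    self._conv_layers.append(ad.Conv1d(
                        c_in, w, spec.kernel_size, rng, length=cur_len))
                    c_in = w
                self._pool_layers.append(ad.MaxPool1d(2))
                self._dropout_layers.append(ad.Dropout(spec.dropout_rate))
                cur_len //= 2
            self._lstm = ad.LSTMLayer(w, h, rng, seq_len=cur_len)
            self._dense_layers.append(ad.Dense(h, h, rng, activation="relu"))
            self._feature_dim = h

    def _build_head(self, rng):
        spec = self.spec
        if spec.head == "direct_sbp_dbp":
            self._head_dim = 2
        elif spec.head == "entire_waveform":
            self._head_dim = spec.window_len
        else:
            self._head_dim = spec.n_classes
        self.head_layer = ad.Dense(self._feature_dim, self._head_dim, rng)

    # -- forward ----------------------------------------------------------
    def _encode(self, x: ad.Tensor, train: bool, rng) -> ad.Tensor:
        spec, fam = self.spec, self.spec.family
        if fam == "fully_connected":
            n = x.shape[0]
            out = x.reshape(n, -1)
            for layer in self._dense_layers:
                out = layer(out)
            return out
        if fam == "lstm":
            return self._lstm(self._decimate(x))
        if fam in ("wavenet", "wavenet_lstm"):
            out = x
            for i, conv in enumerate(self._conv_layers):
                fx = conv(out).relu()
                # residual sum once channel widths match
                out = fx if i == 0 else fx + out
            if fam == "wavenet_lstm":
                return self._lstm(out)
            return out.mean_last()
        # resnet_lstm
        out = x
        idx = 0
        for b, n_convs in enumerate(_RESNET_BLOCK_CONVS):
            skip = None
            for j in range(n_convs):
                out = self._conv_layers[idx](out).relu()
                idx += 1
                if skip is None:
                    # skip taken after the first conv so channel widths
                    # match without an extra projection layer
                    skip = out
            if skip is not out:
                out = out + skip
            out = self._pool_layers[b](out)
            out = self._dropout_layers[b](out, rng=rng, train=train)
        out = self._lstm(out)
        return self._dense_layers[0](out)

    def forward_tensor(self, x: ad.Tensor, train: bool = False,
                       rng=None) -> ad.Tensor:
        """Raw head output on the normalized scale (or logits)."""
        return self.head_layer(self._encode(x, train, rng))

    def _check_and_normalize(self, windows) -> np.ndarray:
        x = np.asarray(windows, dtype=float)
        if x.ndim == 2:
            x = x[:, None, :]
        n_in = self.spec.n_input_channels
        if x.ndim != 3 or x.shape[1] != n_in:
            raise ShapeError(
                f"expected windows of shape (n, {n_in}, L), got {x.shape}")
        if x.shape[2] != self.spec.window_len:
            raise ShapeError(
                f"window length {x.shape[2]} does not match the model's "
                f"configured length {self.spec.window_len}")
        return (x - self.x_mean[None, :, None]) / self.x_std[None, :, None]

    def forward(self, windows) -> np.ndarray:
        """Predictions on the physical scale.

        direct_sbp_dbp -> (n, 2) mmHg [SBP, DBP]; entire_waveform ->
        (n, window_len) mmHg; stage_classifier -> (n, n_classes)
        probabilities.
        """
        x = self._check_and_normalize(windows)
        out = self.forward_tensor(ad.Tensor(x)).data
        if self.spec.head == "stage_classifier":
            return np.apply_along_axis(softmax, 1, out)
        return out * self.y_std + self.y_mean

    __call__ = forward

    # -- bookkeeping ------------------------------------------------------
    def parameters(self):
        params = []
        for layer in (self._conv_layers + self._dense_layers
                      + ([self._lstm] if self._lstm else [])
                      + [self.head_layer]):
            params.extend(layer.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def get_state(self):
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def describe(self) -> dict:
        """Introspect the built layout (layer counts, kernel sizes, rates)."""
        info = {
            "family": self.spec.family,
            "n_conv_layers": len(self._conv_layers),
            "n_pool_layers": len(self._pool_layers),
            "n_lstm_layers": 1 if self._lstm else 0,
            "n_fc_layers": len(self._dense_layers),
            "n_output_layers": 1,
            "conv_kernel_sizes": [c.kernel_size for c in self._conv_layers],
            "pool_sizes": [p.size for p in self._pool_layers],
            "dropout_rates": [d.rate for d in self._dropout_layers],
            "first_layer_input_dim": self._first_layer_input_dim(),
            "n_parameters": self.n_parameters(),
        }
        if self.spec.family in ("wavenet", "wavenet_lstm"):
            info["dilations"] = [c.dilation for c in self._conv_layers]
            info["receptive_field"] = 1 + sum(
                (c.kernel_size - 1) * c.dilation for c in self._conv_layers)
        return info

    def _first_layer_input_dim(self) -> int:
        if self.spec.family == "fully_connected":
            return self._dense_layers[0].in_dim
        if self.spec.family == "lstm":
            return self._lstm.input_size
        return self._conv_layers[0].in_ch

    def cost_breakdown(self) -> list:
        """Per-layer multiply-accumulate counts (1 MAC = 1 FLOP)."""
        entries = []
        for i, c in enumerate(self._conv_layers):
            entries.append((f"conv{i + 1}", c.macs()))
        if self._lstm is not None:
            entries.append(("lstm", self._lstm.macs()))
        for i, d in enumerate(self._dense_layers):
            entries.append((f"fc{i + 1}", d.macs()))
        entries.append(("head", self.head_layer.macs()))
        return entries


def build_model(spec: ModelSpec) -> Model:
    """Instantiate the parameterized network a :class:`ModelSpec` describes."""
    return Model(spec)


def save_model(model: Model, path, group: str = "model") -> None:
    """HDF5 checkpoint: the spec as attributes, one dataset per parameter."""
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for key, value in dataclasses.asdict(model.spec).items():
            g.attrs[key] = value
        params = g.create_group("params")
        for i, p in enumerate(model.parameters()):
            params.create_dataset(f"p{i:03d}", data=p.data)
        stats = g.create_group("stats")
        for key in ("x_mean", "x_std", "y_mean", "y_std"):
            stats.create_dataset(key, data=getattr(model, key))


def load_model(path, group: str = "model") -> Model:
    with h5py.File(path, "r") as f:
        g = f[group]
        kw = {k: (v.item() if hasattr(v, "item") else v)
              for k, v in g.attrs.items()}
        kw["family"] = str(kw["family"])
        for key in ("channels", "head"):
            kw[key] = str(kw[key])
        model = Model(ModelSpec(**kw))
        state = [g["params"][name][()]
                 for name in sorted(g["params"].keys())]
        model.set_state(state)
        for key in ("x_mean", "x_std", "y_mean", "y_std"):
            setattr(model, key, g["stats"][key][()])
    return model


# ---------------------------------------------------------------------------
# Linear baseline: y = m.x + b by least squares
# ---------------------------------------------------------------------------

@dataclass
class LinearBaseline:
    """Least-squares linear regression on flattened windows."""

    m: np.ndarray
    b: np.ndarray

    def predict(self, windows) -> np.ndarray:
        x = np.asarray(windows, dtype=float).reshape(len(windows), -1)
        if x.shape[1] != self.m.shape[0]:
            raise ShapeError(
                f"flattened input length {x.shape[1]} does not match slope "
                f"length {self.m.shape[0]}")
        return x @ self.m + self.b


def fit_linear_baseline(windows, targets) -> LinearBaseline:
    """Fit y = m.x + b on flattened windows by (minimum-norm) least squares."""
    x = np.asarray(windows, dtype=float).reshape(len(windows), -1)
    y = np.asarray(targets, dtype=float)
    if len(x) < 2:
        raise ConfigurationError("fit_linear_baseline requires >= 2 samples")
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    m, _, rank, _ = np.linalg.lstsq(xc, y - y_mean, rcond=None)
    if rank < min(xc.shape):
        warnings.warn(
            "rank-deficient design (constant or collinear inputs); "
            "returning the minimum-norm solution")
    b = y_mean - x_mean @ m
    return LinearBaseline(m=m, b=b)


def hypertension_stage(sbp: float, dbp: float) -> int:
    """Clinical stage from SBP/DBP: 0 normal, 1 elevated, 2 stage-1,
    3 stage-2 hypertension (standard guideline cut-offs)."""
    if sbp >= 140 or dbp >= 90:
        return 3
    if sbp >= 130 or dbp >= 80:
        return 2
    if sbp >= 120:
        return 1
    return 0
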