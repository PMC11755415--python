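"""Forward-pass primitives of the hybrid CNN-LSTM blood-pressure models.

These are the mathematical building blocks the architectures are assembled
from, exposed as plain numpy functions with pinned semantics:

* ``conv2d`` / ``conv1d`` — discrete cross-correlation (the deep-learning
  "convolution"): ``G(x, y) = sum_ij M(x+i, y+j) N(i, j)`` over the valid
  region, then strided.
* ``relu`` — elementwise ``max(0, x)``.
* ``max_pool`` — non-overlapping window maximum (2x2 by default).
* ``lstm_cell`` / ``lstm_sequence`` — the classical LSTM recurrence with
  input, forget and output gates and a tanh candidate state, all acting on
  the concatenation ``[h_prev, x]``.
* ``residual_apply`` — the skip connection ``H(x) = F(x) + x``.
* ``softmax`` — the stable (max-subtracted) probability head.
* ``dense`` — an affine map followed by a named activation.

Everything here is pure and framework-free; the trainable counterparts live
in :mod:`pulseguard.autodiff`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import h5py
import numpy as np
from scipy.signal import correlate, correlate2d
from scipy.special import expit

from .errors import EmptyInputError, ShapeError

__all__ = [
    "ConvSpec",
    "LSTMParams",
    "LSTMState",
    "ResidualBlock",
    "conv2d",
    "conv1d",
    "relu",
    "max_pool",
    "lstm_cell",
    "lstm_sequence",
    "residual_apply",
    "softmax",
    "dense",
    "save_lstm_params",
    "load_lstm_params",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ConvSpec:
    """A correlation kernel with stride and zero-padding.

    ``kernel`` may be a 2-D matrix (for :func:`conv2d`) or a 1-D vector
    (for :func:`conv1d`).
    """

    kernel: np.ndarray
    stride: int = 1
    padding: int = 0

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim not in (1, 2) or min(self.kernel.shape) < 1:
            raise ShapeError("kernel must be a non-empty vector or matrix")
        if self.stride < 1:
            raise ShapeError("stride must be >= 1")
        if self.padding < 0:
            raise ShapeError("padding must be >= 0")


@dataclass
class LSTMState:
    """Cell state C and hidden output h of an LSTM cell."""

    C: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.C.shape != self.h.shape:
            raise ShapeError("C and h must share the hidden size")

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(np.zeros(hidden_size), np.zeros(hidden_size))


@dataclass
class LSTMParams:
    """Weights of one LSTM cell.

    Each weight matrix has shape ``(hidden, hidden + input)`` and acts on
    the concatenation ``[h_prev, x]``; each bias has length ``hidden``.
    With ``tie_candidate_to_input_gate`` the candidate state reuses the
    input-gate parameters instead of ``W_c, b_c`` (a non-standard variant
    some descriptions print; off by default).
    """

    W_i: np.ndarray
    b_i: np.ndarray
    W_c: np.ndarray
    b_c: np.ndarray
    W_f: np.ndarray
    b_f: np.ndarray
    W_o: np.ndarray
    b_o: np.ndarray
    tie_candidate_to_input_gate: bool = False

    def __post_init__(self):
        for name in ("W_i", "W_c", "W_f", "W_o", "b_i", "b_c", "b_f", "b_o"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        h = self.W_i.shape[0]
        for name in ("W_i", "W_c", "W_f", "W_o"):
            w = getattr(self, name)
            if w.ndim != 2 or w.shape != self.W_i.shape:
                raise ShapeError(f"{name} must have shape {self.W_i.shape}")
        for name in ("b_i", "b_c", "b_f", "b_o"):
            b = getattr(self, name)
            if b.shape != (h,):
                raise ShapeError(f"{name} must have length {h} (hidden size)")

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1] - self.hidden_size

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int, **kw) -> "LSTMParams":
        w = np.zeros((hidden_size, hidden_size + input_size))
        b = np.zeros(hidden_size)
        return cls(w, b, w.copy(), b.copy(), w.copy(), b.copy(),
                   w.copy(), b.copy(), **kw)

    @classmethod
    def random(cls, input_size: int, hidden_size: int,
               rng: np.random.Generator, **kw) -> "LSTMParams":
        """Uniform He-style initialization scaled by fan-in."""
        fan_in = hidden_size + input_size
        bound = np.sqrt(6.0 / fan_in)

        def w():
            return rng.uniform(-bound, bound, (hidden_size, fan_in))

        def b():
            return np.zeros(hidden_size)

        return cls(w(), b(), w(), b(), w(), b(), w(), b(), **kw)

    def candidate_params(self):
        if self.tie_candidate_to_input_gate:
            return self.W_i, self.b_i
        return self.W_c, self.b_c


@dataclass
class ResidualBlock:
    """A shape-preserving transform F wrapped in a skip connection.

    ``projection``, when given, is a matrix applied to the input on the
    skip path (used only when F changes the representation size).
    """

    inner: Callable[[np.ndarray], np.ndarray]
    projection: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.projection is not None:
            self.projection = np.asarray(self.projection, dtype=float)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def conv2d(input: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """Strided valid cross-correlation of a matrix with a 2-D kernel."""
    m = np.asarray(input, dtype=float)
    if m.ndim != 2:
        raise ShapeError("conv2d expects a 2-D input matrix")
    if spec.kernel.ndim != 2:
        raise ShapeError("conv2d expects a 2-D kernel")
    if spec.padding:
        m = np.pad(m, spec.padding)
    if m.shape[0] < spec.kernel.shape[0] or m.shape[1] < spec.kernel.shape[1]:
        raise ShapeError("kernel larger than padded input")
    full = correlate2d(m, spec.kernel, mode="valid")
    return full[::spec.stride, ::spec.stride]


def conv1d(input: Sequence[float], spec: ConvSpec) -> np.ndarray:
    """1-D variant of :func:`conv2d`."""
    x = np.asarray(input, dtype=float)
    if x.ndim != 1:
        raise ShapeError("conv1d expects a 1-D input")
    if spec.kernel.ndim != 1:
        raise ShapeError("conv1d expects a 1-D kernel")
    if spec.padding:
        x = np.pad(x, spec.padding)
    if x.size < spec.kernel.size:
        raise ShapeError("kernel larger than padded input")
    return correlate(x, spec.kernel, mode="valid")[::spec.stride]


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def max_pool(input: np.ndarray, window: int = 2, stride: int = None) -> np.ndarray:
    """Non-overlapping window maximum; trailing partial windows are dropped.

    2-D inputs are pooled over ``window x window`` tiles, 1-D inputs over
    length-``window`` runs.  Only ``stride == window`` (the non-overlapping
    case) is supported.
    """
    x = np.asarray(input, dtype=float)
    if stride is not None and stride != window:
        raise ShapeError("max_pool supports only stride == window")
    if x.size == 0:
        raise ShapeError("max_pool input is empty")
    if x.ndim == 1:
        if x.size < window:
            raise ShapeError("max_pool input shorter than window")
        n = x.size // window
        return x[:n * window].reshape(n, window).max(axis=1)
    if x.ndim == 2:
        if x.shape[0] < window or x.shape[1] < window:
            raise ShapeError("max_pool input smaller than window")
        r, c = x.shape[0] // window, x.shape[1] // window
        tiles = x[:r * window, :c * window].reshape(r, window, c, window)
        return tiles.max(axis=(1, 3))
    raise ShapeError("max_pool expects 1-D or 2-D input")


def lstm_cell(x_p: np.ndarray, prev: LSTMState, params: LSTMParams) -> LSTMState:
    """One step of the LSTM recurrence.

    i = sigmoid(W_i [h, x] + b_i);  candidate = tanh(W_c [h, x] + b_c);
    f = sigmoid(W_f [h, x] + b_f);  C' = f * C + i * candidate;
    o = sigmoid(W_o [h, x] + b_o);  h' = o * tanh(C').
    """
    x_p = np.asarray(x_p, dtype=float)
    if x_p.ndim != 1 or x_p.size != params.input_size:
        raise ShapeError(
            f"x_p must be a vector of length {params.input_size} "
            f"(params input size), got shape {x_p.shape}")
    if prev.h.shape != (params.hidden_size,):
        raise ShapeError(
            f"prev state hidden size {prev.h.shape} does not match "
            f"params hidden size {params.hidden_size}")
    z = np.concatenate([prev.h, x_p])
    i_gate = expit(params.W_i @ z + params.b_i)
    w_c, b_c = params.candidate_params()
    candidate = np.tanh(w_c @ z + b_c)
    f_gate = expit(params.W_f @ z + params.b_f)
    c_new = f_gate * prev.C + i_gate * candidate
    o_gate = expit(params.W_o @ z + params.b_o)
    h_new = o_gate * np.tanh(c_new)
    return LSTMState(c_new, h_new)


def lstm_sequence(xs: Sequence[np.ndarray], init: LSTMState,
                  params: LSTMParams) -> list:
    """Left fold of :func:`lstm_cell`; returns every intermediate state."""
    xs = list(xs)
    if len(xs) == 0:
        raise EmptyInputError("lstm_sequence requires a non-empty sequence")
    states = []
    state = init
    for x in xs:
        state = lstm_cell(x, state, params)
        states.append(state)
    return states


def residual_apply(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """The skip connection H(x) = F(x) + x (projected x when shapes differ)."""
    x = np.asarray(x, dtype=float)
    fx = np.asarray(block.inner(x), dtype=float)
    skip = x if block.projection is None else block.projection @ x
    if fx.shape != skip.shape:
        raise ShapeError(
            f"residual inner output shape {fx.shape} does not match skip "
            f"path shape {skip.shape}; provide a projection")
    return fx + skip


def softmax(x: Sequence[float]) -> np.ndarray:
    """Stable softmax: exp(x - max) normalized to sum to one."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise EmptyInputError("softmax requires a non-empty vector")
    e = np.exp(x - x.max())
    return e / e.sum()


_ACTIVATIONS = {
    "linear": lambda x: x,
    "relu": relu,
    "sigmoid": expit,
    "tanh": np.tanh,
    "softmax": softmax,
}


def dense(x: np.ndarray, W: np.ndarray, b: np.ndarray,
          activation: str = "linear") -> np.ndarray:
    """activation(W x + b)."""
    x, W, b = (np.asarray(a, dtype=float) for a in (x, W, b))
    if W.ndim != 2 or W.shape[1] != x.shape[0] or b.shape != (W.shape[0],):
        raise ShapeError(
            f"dense shapes inconsistent: W {W.shape}, x {x.shape}, b {b.shape}")
    if activation not in _ACTIVATIONS:
        raise ShapeError(f"unknown activation '{activation}'")
    return _ACTIVATIONS[activation](W @ x + b)


# ---------------------------------------------------------------------------
# Parameter serialization (HDF5: one group per layer, datasets W/b)
# ---------------------------------------------------------------------------

_GATES = ("i", "c", "f", "o")


def save_lstm_params(params: LSTMParams, path, group: str = "lstm") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for gate in _GATES:
            sub = g.create_group(gate)
            sub.create_dataset("W", data=getattr(params, f"W_{gate}"))
            sub.create_dataset("b", data=getattr(params, f"b_{gate}"))
        g.attrs["tie_candidate_to_input_gate"] = params.tie_candidate_to_input_gate


def load_lstm_params(path, group: str = "lstm") -> LSTMParams:
    with h5py.File(path, "r") as f:
        g = f[group]
        kw = {}
        for gate in _GATES:
            kw[f"W_{gate}"] = g[gate]["W"][()]
            kw[f"b_{gate}"] = g[gate]["b"][()]
        tie = bool(g.attrs.get("tie_candidate_to_input_gate", False))
    return LSTMParams(tie_candidate_to_input_gate=tie, **kw)
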