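"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its networks with this small tape-based engine: each
:class:`Tensor` wraps an ``ndarray`` and records the backward closure of the
operation that produced it, so a topological sweep from the loss accumulates
gradients into every parameter.  Only the forward operations the
architectures need are provided (elementwise arithmetic, matmul, sigmoid /
tanh / relu, 1-D convolution, max-pooling, dropout, reductions, concat and
slicing), plus the trainable layer classes built from them and an Adam
optimizer.  Forward semantics of the underlying primitives are pinned and
oracle-tested in :mod:`pulseguard.nn_core`; this module is the trainable
counterpart.  The engine computes in single precision (the standard choice
for network training); the contract-pinned nn_core primitives stay in
double precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import ShapeError

DTYPE = np.float32

__all__ = [
    "Tensor",
    "concat",
    "Dense",
    "Conv1d",
    "MaxPool1d",
    "AvgDecimate1d",
    "Dropout",
    "LSTMLayer",
    "Adam",
    "mse_loss",
    "softmax_cross_entropy",
    "he_uniform",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node of the computation tape: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- tape helpers -----------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=DTYPE)
        else:
            self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __pow__(self, exponent):
        exponent = float(exponent)
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- activations ------------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = expit(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old_shape = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, key):
        # basic (slice/integer) indexing only: positions are unique, so a
        # buffered += suffices for the scatter
        out_data = self.data[key]

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[key] += g

        return self._make(out_data, (self,), backward)

    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g))

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g / n))

        return self._make(self.data.mean(), (self,), backward)

    # -- backward sweep ---------------------------------------------------
    def backward(self):
        if self.data.ndim != 0:
            raise ShapeError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors, axis=0):
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride=1, dilation=1,
           pad_left=0, pad_right=0) -> Tensor:
    """Batched 1-D cross-correlation: x (N,Cin,L), weight (Cout,Cin,K)."""
    n, c_in, length = x.data.shape
    c_out, c_in_w, k = weight.data.shape
    if c_in_w != c_in:
        raise ShapeError(
            f"conv1d weight expects {c_in_w} input channels, got {c_in}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    lp = xp.shape[-1]
    span = (k - 1) * dilation + 1
    if lp < span:
        raise ShapeError("conv1d kernel span exceeds padded input length")
    l_out = (lp - span) // stride + 1
    # per-tap formulation: K strided slices, each contracted with one
    # kernel column -- no im2col materialization
    out = np.empty((n, l_out, c_out), dtype=DTYPE)
    out[:] = bias.data
    for tap in range(k):
        start = tap * dilation
        sl = xp[:, :, start:start + (l_out - 1) * stride + 1:stride]
        out += np.matmul(sl.transpose(0, 2, 1), weight.data[:, :, tap].T)
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        need_x = x.requires_grad
        gxp = np.zeros_like(xp) if need_x else None
        for tap in range(k):
            start = tap * dilation
            stop = start + (l_out - 1) * stride + 1
            if weight.requires_grad:
                sl = xp[:, :, start:stop:stride]
                if weight.grad is None:
                    weight.grad = np.zeros_like(weight.data)
                # (N,O,L) x (N,L,C) batched, then summed over the batch
                weight.grad[:, :, tap] += np.matmul(
                    g, sl.transpose(0, 2, 1)).sum(axis=0)
            if need_x:
                gxp[:, :, start:stop:stride] += np.matmul(
                    weight.data[:, :, tap].T, g)
        if need_x:
            x._accumulate(gxp[:, :, pad_left:lp - pad_right if pad_right else lp])

    return Tensor._make(out_data, (x, weight, bias), backward)


def maxpool1d(x: Tensor, size=2) -> Tensor:
    """Non-overlapping max pooling over the trailing axis."""
    n, c, length = x.data.shape
    l_out = length // size
    if l_out == 0:
        raise ShapeError("maxpool1d input shorter than pool window")
    trimmed = x.data[:, :, :l_out * size].reshape(n, c, l_out, size)
    arg = trimmed.argmax(axis=-1)
    out_data = np.take_along_axis(trimmed, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros((n, c, l_out, size), dtype=DTYPE)
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
            full = np.zeros_like(x.data)
            full[:, :, :l_out * size] = gx.reshape(n, c, l_out * size)
            x._accumulate(full)

    return Tensor._make(out_data, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0.0:
        return x
    mask = ((rng.random(x.data.shape, dtype=np.float32) >= rate)
            / np.float32(1.0 - rate))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2).mean()


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logp = z - zmax - np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            probs = np.exp(logp)
            probs[np.arange(n), labels] -= 1.0
            logits._accumulate(g * probs / n)

    return Tensor._make(np.asarray(loss, dtype=DTYPE), (logits,), backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Uniform He-style initialization scaled by fan-in."""
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base layer: parameter bookkeeping plus a static MAC count."""

    def parameters(self):
        return [v for v in vars(self).values() if isinstance(v, Tensor)
                and v.requires_grad]

    def macs(self) -> int:
        return 0


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng, activation="linear"):
        self.W = Tensor(he_uniform(rng, (in_dim, out_dim), in_dim),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.activation = activation
        self.in_dim, self.out_dim = in_dim, out_dim

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "tanh":
            out = out.tanh()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        return out

    def macs(self):
        return self.in_dim * self.out_dim


class Conv1d(Layer):
    def __init__(self, in_ch, out_ch, kernel_size, rng, stride=1, dilation=1,
                 causal=False, length=None):
        fan_in = in_ch * kernel_size
        self.W = Tensor(he_uniform(rng, (out_ch, in_ch, kernel_size), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.dilation, self.causal = stride, dilation, causal
        self.kernel_size, self.in_ch, self.out_ch = kernel_size, in_ch, out_ch
        self.length = length  # output length when built for a fixed window

    def __call__(self, x: Tensor) -> Tensor:
        span = (self.kernel_size - 1) * self.dilation
        if self.causal:
            pl, pr = span, 0
        else:  # 'same' padding for stride 1
            pl, pr = span // 2, span - span // 2
        return conv1d(x, self.W, self.b, stride=self.stride,
                      dilation=self.dilation, pad_left=pl, pad_right=pr)

    def macs(self):
        length = self.length if self.length is not None else 1
        return self.in_ch * self.out_ch * self.kernel_size * length


class MaxPool1d(Layer):
    def __init__(self, size=2):
        self.size = size

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.size)


class AvgDecimate1d(Layer):
    """Non-overlapping average pooling used to decimate long sequences."""

    def __init__(self, factor):
        self.factor = factor

    def __call__(self, x: Tensor) -> Tensor:
        n, c, length = x.shape
        f = self.factor
        l_out = length // f
        return x[:, :, :l_out * f].reshape(n, c, l_out, f).mean_last()


# mean over trailing axis, needed by AvgDecimate1d
def _mean_last(self):
    out_data = self.data.mean(axis=-1)
    k = self.data.shape[-1]

    def backward(g):
        if self.requires_grad:
            self._accumulate(np.repeat(g[..., None], k, axis=-1) / k)

    return Tensor._make(out_data, (self,), backward)


Tensor.mean_last = _mean_last


class Dropout(Layer):
    def __init__(self, rate):
        self.rate = rate

    def __call__(self, x: Tensor, rng=None, train=False) -> Tensor:
        if train and rng is not None:
            return dropout(x, self.rate, rng)
        return x


class LSTMLayer(Layer):
    """Single LSTM layer over (N, C, T); returns the final hidden state.

    Gate parameterization mirrors the classical cell: separate input,
    candidate, forget and output weights acting on the concatenation
    [h_{t-1}, x_t].
    """

    def __init__(self, input_size, hidden_size, rng, seq_len=None):
        fan_in = hidden_size + input_size
        def w():
            return Tensor(he_uniform(rng, (fan_in, hidden_size), fan_in),
                          requires_grad=True)
        self.Wi, self.Wc, self.Wf, self.Wo = w(), w(), w(), w()
        self.bi = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.bc = Tensor(np.zeros(hidden_size), requires_grad=True)
        # forget bias of 1 keeps early memory open, a standard choice
        self.bf = Tensor(np.ones(hidden_size), requires_grad=True)
        self.bo = Tensor(np.zeros(hidden_size), requires_grad=True)
        self.input_size, self.hidden_size = input_size, hidden_size
        self.seq_len = seq_len

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t_steps = x.shape
        h = Tensor(np.zeros((n, self.hidden_size)))
        cell = Tensor(np.zeros((n, self.hidden_size)))
        for t in range(t_steps):
            xt = x[:, :, t]
            z = concat([h, xt], axis=1)
            i_gate = (z @ self.Wi + self.bi).sigmoid()
            cand = (z @ self.Wc + self.bc).tanh()
            f_gate = (z @ self.Wf + self.bf).sigmoid()
            cell = f_gate * cell + i_gate * cand
            o_gate = (z @ self.Wo + self.bo).sigmoid()
            h = o_gate * cell.tanh()
        return h

    def macs(self):
        steps = self.seq_len if self.seq_len is not None else 1
        per_step = 4 * (self.hidden_size + self.input_size) * self.hidden_size
        return per_step * steps


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
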