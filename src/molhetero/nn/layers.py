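"""Network layers built on the autodiff tensor: Dense, BatchNorm, LSTM, Conv.

Layers hold their parameters as :class:`~molhetero.nn.tensor.Tensor` objects
with ``requires_grad=True`` and expose ``parameters()`` for optimizers and
``get_weights``/``set_weights`` for checkpointing and model splitting.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

# ---------------------------------------------------------------------------
# initializers

def _fans(shape: tuple[int, ...]) -> tuple[int, int]:
    if len(shape) == 2:
        return shape[0], shape[1]
    # conv kernels (kh, kw, c_in, c_out)
    receptive = int(np.prod(shape[:-2]))
    return shape[-2] * receptive, shape[-1] * receptive


def initialize(shape, scheme: str, rng: np.random.Generator) -> np.ndarray:
    fan_in, fan_out = _fans(shape)
    if scheme == "glorot_uniform":
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)
    if scheme == "glorot_normal":
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)
    if scheme == "he_uniform":
        lim = np.sqrt(6.0 / fan_in)
        return rng.uniform(-lim, lim, size=shape)
    if scheme == "he_normal":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    if scheme == "lecun_uniform":
        lim = np.sqrt(3.0 / fan_in)
        return rng.uniform(-lim, lim, size=shape)
    if scheme == "lecun_normal":
        return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape)
    if scheme == "orthogonal":
        a = rng.normal(size=(max(shape), max(shape)))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        return q[: shape[0], : shape[1]]
    raise ValueError(f"unknown initializer {scheme!r}")


INITIALIZERS = (
    "lecun_uniform",
    "glorot_uniform",
    "he_uniform",
    "lecun_normal",
    "glorot_normal",
    "he_normal",
)


class Module:
    """Base class: parameter bookkeeping shared by all layers/models."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 rng: np.random.Generator | None = None,
                 initializer: str = "glorot_uniform"):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(initialize((n_in, n_out), initializer, rng),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight + self.bias
        if self.activation == "relu":
            return T.relu(y)
        if self.activation == "tanh":
            return T.tanh(y)
        if self.activation == "selu":
            return T.selu(y)
        if self.activation is None or self.activation == "linear":
            return y
        raise ValueError(f"unknown activation {self.activation!r}")


class BatchNorm(Module):
    """Batch normalization over the leading axis with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2.0).mean(axis=0, keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data.ravel())
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data.ravel())
            inv = (var + self.eps) ** -0.5
            return centered * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta


class LSTM(Module):
    """Single LSTM layer processing (N, T, D) one-hot/real sequences.

    Gate layout in the fused weight matrices is [i, f, g, o]. The forget
    gate bias starts at 1, the usual trick to ease gradient flow early in
    training.
    """

    def __init__(self, n_in: int, n_hidden: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_in = n_in
        self.n_hidden = n_hidden
        self.w_x = Tensor(initialize((n_in, 4 * n_hidden), "glorot_uniform", rng),
                          requires_grad=True)
        # recurrent kernel orthogonal per block, the standard LSTM choice
        w_h = np.concatenate(
            [initialize((n_hidden, n_hidden), "orthogonal", rng)
             for _ in range(4)], axis=1)
        self.w_h = Tensor(w_h, requires_grad=True)
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden : 2 * n_hidden] = 1.0
        self.bias = Tensor(bias, requires_grad=True)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        nh = self.n_hidden
        xw = x_t @ self.w_x + self.bias
        hc = T.lstm_step_fused(xw, h, c, self.w_h)
        return hc[:, :nh], hc[:, nh:]

    def run(
        self,
        x: Tensor,
        h0: Tensor | None = None,
        c0: Tensor | None = None,
        reverse: bool = False,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Run over time; returns (h outputs (N,T,H) in input order, h_T, c_T)."""
        n, t_steps, _ = x.shape
        nh = self.n_hidden
        h = h0 if h0 is not None else Tensor(np.zeros((n, nh)))
        c = c0 if c0 is not None else Tensor(np.zeros((n, nh)))
        seq = T.lstm_sequence(x, self.w_x, self.w_h, self.bias, h, c,
                              reverse=reverse)
        final = 0 if reverse else t_steps - 1
        return (seq[:, :, :nh], seq[:, final, :nh], seq[:, final, nh:])

    def run_states(self, x: Tensor, h0: Tensor | None = None,
                   c0: Tensor | None = None) -> Tensor:
        """Full (N, T, 2H) [h_t, c_t] sequence (for position-gathered states)."""
        n = x.shape[0]
        h = h0 if h0 is not None else Tensor(np.zeros((n, self.n_hidden)))
        c = c0 if c0 is not None else Tensor(np.zeros((n, self.n_hidden)))
        return T.lstm_sequence(x, self.w_x, self.w_h, self.bias, h, c)


class BiLSTM(Module):
    """Bidirectional LSTM: forward and backward layers, outputs concatenated."""

    def __init__(self, n_in: int, n_hidden: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng)
        self.n_hidden = n_hidden

    def run(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns per-step concatenated outputs and concatenated (h, c)."""
        out_f, h_f, c_f = self.fwd.run(x)
        out_b, h_b, c_b = self.bwd.run(x, reverse=True)
        outs = T.concat([out_f, out_b], axis=2)
        return outs, T.concat([h_f, h_b], axis=1), T.concat([c_f, c_b], axis=1)


class Conv2D(Module):
    def __init__(self, c_in: int, filters: int, kernel: int, stride: int = 1,
                 activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            initialize((kernel, kernel, c_in, filters), "glorot_uniform", rng),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(filters), requires_grad=True)
        self.stride = stride
        self.activation = activation
        self.filters = filters

    def __call__(self, x: Tensor) -> Tensor:
        y = T.conv2d(x, self.weight, self.bias, stride=self.stride)
        return T.relu(y) if self.activation == "relu" else y
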