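"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only what the encoder/decoder networks and the QSAR feed-forward nets
need: broadcasting arithmetic, matmul, the usual activations, reductions,
shape ops, a fused masked softmax cross-entropy, dropout and 2D
convolution/pooling. Gradients are accumulated by a topological backward
pass; correctness is pinned by numerical gradient checks in the tests.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True

#: numpy dtype for all tensor data; float64 by default for test-grade
#: numerics, switchable to float32 for faster large training runs
DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    global DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return DTYPE


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * _as_tensor(other) ** (-1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = backward if _GRAD_ENABLED else None
        return out

    # -- shape -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward if _GRAD_ENABLED else None
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(gg, self.data.shape)
            self._accumulate(np.ascontiguousarray(grad))

        out._backward = backward if _GRAD_ENABLED else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ------------------------------------------------

def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))

    def backward(g):
        x._accumulate(g * (1.0 - y * y))

    out._backward = backward if _GRAD_ENABLED else None
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # tanh form avoids exp overflow for large negative inputs
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def sigmoid(x: Tensor) -> Tensor:
    y = _sigmoid(x.data)
    out = Tensor(y, parents=(x,))

    def backward(g):
        x._accumulate(g * y * (1.0 - y))

    out._backward = backward if _GRAD_ENABLED else None
    return out


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    out = Tensor(y, parents=(x,))

    def backward(g):
        x._accumulate(g * (x.data > 0.0))

    out._backward = backward if _GRAD_ENABLED else None
    return out


_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def selu(x: Tensor) -> Tensor:
    pos = x.data > 0.0
    exp_neg = np.exp(np.minimum(x.data, 0.0))  # exp only on the neg branch
    y = _SELU_SCALE * np.where(pos, x.data, _SELU_ALPHA * (exp_neg - 1.0))
    out = Tensor(y, parents=(x,))

    def backward(g):
        dy = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * exp_neg)
        x._accumulate(g * dy)

    out._backward = backward if _GRAD_ENABLED else None
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    out = Tensor(y, parents=(x,))

    def backward(g):
        x._accumulate(g * y)

    out._backward = backward if _GRAD_ENABLED else None
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))

    def backward(g):
        x._accumulate(g / x.data)

    out._backward = backward if _GRAD_ENABLED else None
    return out


def sqrt(x: Tensor) -> Tensor:
    return x**0.5


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = backward if _GRAD_ENABLED else None
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out._backward = backward if _GRAD_ENABLED else None
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (inference-side; no graph)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, target_indices: np.ndarray, mask: np.ndarray | None = None
) -> Tensor:
    """Mean masked categorical cross-entropy over class logits.

    ``logits`` has shape (..., V); ``target_indices`` the matching integer
    class array; ``mask`` (same shape as targets) weights positions, and
    the loss is averaged over the mask sum (non-pad positions).
    """
    p = softmax(logits.data, axis=-1)
    flat_p = p.reshape(-1, p.shape[-1])
    tgt = np.asarray(target_indices).reshape(-1)
    if mask is None:
        w = np.ones_like(tgt, dtype=np.float64)
    else:
        w = np.asarray(mask, dtype=np.float64).reshape(-1)
    denom = max(w.sum(), 1.0)
    picked = flat_p[np.arange(tgt.size), tgt]
    loss_val = -(w * np.log(np.maximum(picked, 1e-300))).sum() / denom
    out = Tensor(loss_val, parents=(logits,))

    def backward(g):
        grad = flat_p.copy()
        grad[np.arange(tgt.size), tgt] -= 1.0
        grad *= (w / denom)[:, None]
        logits._accumulate(g * grad.reshape(logits.data.shape))

    out._backward = backward if _GRAD_ENABLED else None
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    return x * Tensor(mask)


def lstm_sequence(
    x: Tensor,
    w_x: Tensor,
    w_h: Tensor,
    bias: Tensor,
    h0: Tensor,
    c0: Tensor,
    reverse: bool = False,
) -> Tensor:
    """A whole LSTM layer pass as one graph node (loop fused into numpy).

    ``x`` is (N, T, D); returns (N, T, 2H) holding [h_t, c_t] at each step
    (in input time order even when ``reverse`` is set). The backward pass
    is hand-written backpropagation through time accepting gradients on
    every step's h and c, so callers can slice out step outputs, the final
    states, or both, with at most a couple of cheap view nodes.
    """
    n, t_steps, d = x.data.shape
    nh = h0.data.shape[1]
    xw_all = x.data.reshape(n * t_steps, d) @ w_x.data + bias.data
    xw_all = xw_all.reshape(n, t_steps, 4 * nh)
    order = (range(t_steps - 1, -1, -1) if reverse else range(t_steps))
    h, c = h0.data, c0.data
    dt = x.data.dtype
    hs_prev = np.empty((n, t_steps, nh), dtype=dt)  # h_{t-1} (for dw_h)
    cs_prev = np.empty((n, t_steps, nh), dtype=dt)
    gates_i = np.empty((n, t_steps, nh), dtype=dt)
    gates_f = np.empty((n, t_steps, nh), dtype=dt)
    gates_g = np.empty((n, t_steps, nh), dtype=dt)
    gates_o = np.empty((n, t_steps, nh), dtype=dt)
    tanh_cs = np.empty((n, t_steps, nh), dtype=dt)
    out_data = np.empty((n, t_steps, 2 * nh), dtype=dt)
    for t in order:
        gates = xw_all[:, t, :] + h @ w_h.data
        i = _sigmoid(gates[:, 0:nh])
        f = _sigmoid(gates[:, nh : 2 * nh])
        g = np.tanh(gates[:, 2 * nh : 3 * nh])
        o = _sigmoid(gates[:, 3 * nh :])
        hs_prev[:, t], cs_prev[:, t] = h, c
        c = f * c + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        gates_i[:, t], gates_f[:, t] = i, f
        gates_g[:, t], gates_o[:, t] = g, o
        tanh_cs[:, t] = tanh_c
        out_data[:, t, :nh], out_data[:, t, nh:] = h, c
    out = Tensor(out_data, parents=(x, w_x, w_h, bias, h0, c0))

    def backward(grad):
        dxw = np.empty_like(xw_all)
        dw_h = np.zeros_like(w_h.data)
        dh_next = np.zeros((n, nh), dtype=dt)
        dc_next = np.zeros((n, nh), dtype=dt)
        for t in reversed(list(order)):
            gh = grad[:, t, :nh] + dh_next
            gc = grad[:, t, nh:] + dc_next
            i, f = gates_i[:, t], gates_f[:, t]
            g, o = gates_g[:, t], gates_o[:, t]
            tanh_c = tanh_cs[:, t]
            dc = gh * o * (1.0 - tanh_c * tanh_c) + gc
            dgates = np.concatenate(
                [
                    dc * g * i * (1.0 - i),
                    dc * cs_prev[:, t] * f * (1.0 - f),
                    dc * i * (1.0 - g * g),
                    gh * tanh_c * o * (1.0 - o),
                ],
                axis=1,
            )
            dxw[:, t, :] = dgates
            dw_h += hs_prev[:, t].T @ dgates
            dh_next = dgates @ w_h.data.T
            dc_next = dc * f
        w_h._accumulate(dw_h)
        h0._accumulate(dh_next)
        c0._accumulate(dc_next)
        dxw_flat = dxw.reshape(n * t_steps, 4 * nh)
        bias._accumulate(dxw_flat.sum(axis=0))
        w_x._accumulate(x.data.reshape(n * t_steps, d).T @ dxw_flat)
        x._accumulate((dxw_flat @ w_x.data.T).reshape(n, t_steps, d))

    out._backward = backward if _GRAD_ENABLED else None
    return out


def lstm_step_fused(xw_t: Tensor, h: Tensor, c: Tensor, w_h: Tensor) -> Tensor:
    """One LSTM step as a single graph node.

    ``xw_t`` is the precomputed input projection x_t @ W_x + bias of shape
    (B, 4H); gate layout [i, f, g, o]. Returns the concatenation
    [h_new, c_new] of shape (B, 2H); the hand-written backward covers both
    halves in one pass, which is why this exists (the op-by-op version
    spends most of its time in Python node bookkeeping).
    """
    nh = h.data.shape[1]
    gates = xw_t.data + h.data @ w_h.data
    i = _sigmoid(gates[:, 0:nh])
    f = _sigmoid(gates[:, nh : 2 * nh])
    g = np.tanh(gates[:, 2 * nh : 3 * nh])
    o = _sigmoid(gates[:, 3 * nh :])
    c_new = f * c.data + i * g
    tanh_c = np.tanh(c_new)
    h_new = o * tanh_c
    out = Tensor(np.concatenate([h_new, c_new], axis=1),
                 parents=(xw_t, h, c, w_h))

    def backward(grad):
        gh, gc = grad[:, :nh], grad[:, nh:]
        dc = gh * o * (1.0 - tanh_c * tanh_c) + gc
        do = gh * tanh_c
        dgates = np.concatenate(
            [
                dc * g * i * (1.0 - i),
                dc * c.data * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        xw_t._accumulate(dgates)
        h._accumulate(dgates @ w_h.data.T)
        c._accumulate(dc * f)
        w_h._accumulate(h.data.T @ dgates)

    out._backward = backward if _GRAD_ENABLED else None
    return out


# -- 2D convolution / pooling (NHWC, 'same' padding) ----------------------

def _pad_same(x: np.ndarray, kh: int, kw: int, stride: int):
    h, w = x.shape[1], x.shape[2]
    out_h = -(-h // stride)
    out_w = -(-w // stride)
    pad_h = max((out_h - 1) * stride + kh - h, 0)
    pad_w = max((out_w - 1) * stride + kw - w, 0)
    pads = (
        (0, 0),
        (pad_h // 2, pad_h - pad_h // 2),
        (pad_w // 2, pad_w - pad_w // 2),
        (0, 0),
    )
    return pads, out_h, out_w


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    pads, out_h, out_w = _pad_same(x, kh, kw, stride)
    xp = np.pad(x, pads)
    n, _, _, c = xp.shape
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, out_h, out_w, kh, kw, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    cols = windows.reshape(n * out_h * out_w, kh * kw * c)
    return cols, xp.shape, pads, out_h, out_w


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """'same'-padded 2D convolution. x: (N,H,W,C); weight: (kh,kw,C,F)."""
    kh, kw, c_in, f = weight.data.shape
    cols, xp_shape, pads, out_h, out_w = _im2col(x.data, kh, kw, stride)
    wmat = weight.data.reshape(-1, f)
    out_data = cols @ wmat + bias.data
    n = x.data.shape[0]
    out = Tensor(out_data.reshape(n, out_h, out_w, f), parents=(x, weight, bias))

    def backward(g):
        gflat = g.reshape(-1, f)
        weight._accumulate((cols.T @ gflat).reshape(weight.data.shape))
        bias._accumulate(gflat.sum(axis=0))
        gcols = gflat @ wmat.T  # (N*oh*ow, kh*kw*C)
        gxp = np.zeros(xp_shape, dtype=x.data.dtype)
        gcols = gcols.reshape(n, out_h, out_w, kh, kw, c_in)
        for i in range(kh):
            for j in range(kw):
                gxp[:, i : i + out_h * stride : stride,
                    j : j + out_w * stride : stride, :] += gcols[:, :, :, i, j, :]
        (ph0, ph1), (pw0, pw1) = pads[1], pads[2]
        h, w = x.data.shape[1], x.data.shape[2]
        x._accumulate(gxp[:, ph0 : ph0 + h, pw0 : pw0 + w, :])

    out._backward = backward if _GRAD_ENABLED else None
    return out


def maxpool2d(x: Tensor, size: int = 3, stride: int = 1) -> Tensor:
    """'same'-padded max pooling over (N,H,W,C)."""
    pads, out_h, out_w = _pad_same(x.data, size, size, stride)
    xp = np.pad(x.data, pads, constant_values=-np.inf)
    n, _, _, c = xp.shape
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, out_h, out_w, size, size, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    flat = windows.reshape(n, out_h, out_w, size * size, c)
    arg = flat.argmax(axis=3)
    out_data = np.take_along_axis(flat, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        gxp = np.zeros(xp.shape, dtype=x.data.dtype)
        ki, kj = np.divmod(arg, size)
        ni, oi, oj, ci = np.indices(arg.shape)
        np.add.at(gxp, (ni, oi * stride + ki, oj * stride + kj, ci), g)
        (ph0, _), (pw0, _) = pads[1], pads[2]
        h, w = x.data.shape[1], x.data.shape[2]
        x._accumulate(gxp[:, ph0 : ph0 + h, pw0 : pw0 + w, :])

    out._backward = backward if _GRAD_ENABLED else None
    return out
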