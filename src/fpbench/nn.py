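"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine carrying exactly the operations the
graph autoencoder and the SMILES variational autoencoder need: broadcasting
arithmetic, (batched) matmul, ReLU/SELU/sigmoid/tanh/softmax, slicing and
concatenation, 1-D convolution via im2col, dropout, binary cross-entropy with
optional masking, plus Adam and a halving-on-plateau learning-rate schedule.
Everything is float64 and deterministic given a seeded ``numpy`` Generator.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float64

# SELU constants (Klambauer et al. 2017)
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph machinery ---------------------------------------------------

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        out = Tensor(a.data + b.data, (a, b))
        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        out = Tensor(a.data * b.data, (a, b))
        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        a, b = self, Tensor._wrap(other)
        out = Tensor(a.data @ b.data, (a, b))
        def back(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        out._backward = back
        return out

    def transpose_last2(self) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, -1, -2), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.swapaxes(g, -1, -2))
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(orig))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], (self,))
        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = back
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def back(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0))
        return out

    def selu(self) -> "Tensor":
        pos = self.data > 0
        y = _SELU_SCALE * np.where(pos, self.data, _SELU_ALPHA * (np.exp(self.data) - 1.0))
        out = Tensor(y, (self,))
        def back(g):
            if self.requires_grad:
                d = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * np.exp(self.data))
                self._accum(g * d)
        out._backward = back
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1.0 - y))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y * y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, (self,))
        def back(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))
        out._backward = back
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool = True) -> "Tensor":
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p == 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in parts], axis=axis), tuple(parts))
    sizes = [t.data.shape[axis] for t in parts]
    splits = np.cumsum(sizes)[:-1]
    def back(g):
        for t, piece in zip(parts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = back
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 1-D convolution.

    ``x``: (batch, length, c_in); ``w``: (kernel, c_in, c_out); ``b``: (c_out,).
    Output: (batch, length - kernel + 1, c_out).
    """
    bsz, length, c_in = x.data.shape
    k, _, c_out = w.data.shape
    l_out = length - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)  # (B, Lout, Cin, k)
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(bsz, l_out, k * c_in)
    w2 = w.data.reshape(k * c_in, c_out)
    out = Tensor(win @ w2 + b.data, (x, w, b))
    def back(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))
        if w.requires_grad:
            gw2 = np.einsum("blk,blo->ko", win, g)
            w._accum(gw2.reshape(k, c_in, c_out))
        if x.requires_grad:
            gwin = (g @ w2.T).reshape(bsz, l_out, k, c_in)
            gx = np.zeros_like(x.data)
            for i in range(k):
                gx[:, i:i + l_out, :] += gwin[:, :, i, :]
            x._accum(gx)
    out._backward = back
    return out


def gru_step(x: Tensor, h: Tensor, wx: Tensor, wh: Tensor,
             bx: Tensor, bh: Tensor) -> Tensor:
    """One fused GRU cell update ``h' = (1-z) n + z h`` with a closed-form backward.

    Gate layout along the last axis of ``wx``/``wh`` (width 3H) is
    reset | update | candidate.  Fusing the ~20 elementwise/matmul tape nodes
    of a step into one keeps the 140-step decoder graph small.
    """
    hh = h.data.shape[-1]
    gx = x.data @ wx.data + bx.data
    gh = h.data @ wh.data + bh.data
    r = 1.0 / (1.0 + np.exp(-(gx[:, :hh] + gh[:, :hh])))
    z = 1.0 / (1.0 + np.exp(-(gx[:, hh:2 * hh] + gh[:, hh:2 * hh])))
    ghn = gh[:, 2 * hh:]
    n = np.tanh(gx[:, 2 * hh:] + r * ghn)
    out = Tensor((1.0 - z) * n + z * h.data, (x, h, wx, wh, bx, bh))

    def back(g):
        dz = g * (h.data - n) * z * (1.0 - z)
        dn = g * (1.0 - z) * (1.0 - n * n)
        dr = dn * ghn * r * (1.0 - r)
        dgx = np.concatenate([dr, dz, dn], axis=1)
        dgh = np.concatenate([dr, dz, dn * r], axis=1)
        if bx.requires_grad:
            bx._accum(dgx.sum(axis=0))
        if bh.requires_grad:
            bh._accum(dgh.sum(axis=0))
        if wx.requires_grad:
            wx._accum(x.data.T @ dgx)
        if wh.requires_grad:
            wh._accum(h.data.T @ dgh)
        if x.requires_grad:
            x._accum(dgx @ wx.data.T)
        if h.requires_grad:
            h._accum(dgh @ wh.data.T + g * z)
    out._backward = back
    return out


def bce(p: Tensor, target: np.ndarray, mask: np.ndarray | None = None,
        eps: float = 1e-7) -> Tensor:
    """Mean elementwise binary cross-entropy of probabilities against (soft) targets.

    ``target`` entries may lie anywhere in [0, 1].  With a ``mask``, the mean
    runs over masked-in entries only.
    """
    t = np.asarray(target, dtype=DTYPE)
    pc = np.clip(p.data, eps, 1.0 - eps)
    elem = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc))
    if mask is None:
        value = elem.mean()
        scale = 1.0 / elem.size
        m = None
    else:
        m = np.asarray(mask, dtype=DTYPE)
        total = m.sum()
        value = float((elem * m).sum() / total)
        scale = 1.0 / total
    out = Tensor(value, (p,))
    def back(g):
        if p.requires_grad:
            d = (-(t / pc) + (1.0 - t) / (1.0 - pc)) * scale
            d = d * (np.abs(p.data - np.clip(p.data, eps, 1.0 - eps)) == 0)
            if m is not None:
                d = d * m
            p._accum(g * d)
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# parameters, init, optimization


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator,
                   fan_in: int | None = None, fan_out: int | None = None) -> Tensor:
    """Glorot/Xavier uniform initialization."""
    if fan_in is None:
        fan_in = int(np.prod(shape[:-1]))
    if fan_out is None:
        fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauHalving:
    """Halve the learning rate when the epoch loss fails to improve.

    Training halts once the rate reaches ``floor`` (or the loss reaches zero,
    checked by the caller).
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5, floor: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.floor = floor
        self.best = np.inf

    def step(self, epoch_loss: float) -> None:
        if epoch_loss < self.best:
            self.best = epoch_loss
        else:
            self.opt.lr = max(self.opt.lr * self.factor, 0.0)

    @property
    def halted(self) -> bool:
        return self.opt.lr <= self.floor


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""
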