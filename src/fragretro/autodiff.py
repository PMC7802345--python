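"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for recurrent encoder–decoder networks: broadcasting
elementwise arithmetic, (batched) matrix products, the LSTM gate
nonlinearities, masked softmax, embedding lookup with scatter-add backward,
and a fused masked cross-entropy.  Graphs are built eagerly; ``backward()``
runs an iterative topological sweep so deep unrolled recurrences do not hit
the recursion limit.  Gradients accumulate in place into preallocated
buffers — sliced writes go straight into the parent's buffer — which keeps
the per-timestep cost of unrolled sequences linear.

Arrays are float32 by default (training); tests that compare against
numerical derivatives switch to float64 via :func:`set_dtype`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "embedding", "index_time",
           "cross_entropy_sum", "lstm_cell", "set_dtype", "get_dtype"]

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global array dtype (float32 for speed, float64 for checks)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def _ensure_grad(self) -> np.ndarray:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ---- graph traversal ----------------------------------------------
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data - other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(-_unbroadcast(out.grad, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / (other.data ** 2),
                                          other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __neg__(self):
        def backward(out):
            self._accum(-out.grad)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        """``a @ b`` with NumPy matmul broadcasting over leading axes."""
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(out):
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim == 3:
                    # shared weight against a batched input: fold batch into rows
                    a = self.data.reshape(-1, self.data.shape[-1])
                    g = out.grad.reshape(-1, out.grad.shape[-1])
                    other._ensure_grad()
                    other.grad += a.T @ g
                else:
                    g = np.swapaxes(self.data, -1, -2) @ out.grad
                    other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    __matmul__ = matmul

    # ---- elementwise nonlinearities ------------------------------------
    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(out):
            self._accum(out.grad * (1.0 - out.data * out.data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            self._accum(out.grad * out.data * (1.0 - out.data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(out):
            self._accum(out.grad * out.data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def square(self) -> "Tensor":
        def backward(out):
            self._accum(out.grad * 2.0 * self.data)

        return Tensor(self.data * self.data, parents=(self,), backward=backward)

    # ---- shape ops ------------------------------------------------------
    def slice(self, key) -> "Tensor":
        """Basic (non-repeating) indexing; gradient adds into the slice."""
        out_data = self.data[key]

        def backward(out):
            self._ensure_grad()[key] += out.grad

        return Tensor(out_data, parents=(self,), backward=backward)

    def __getitem__(self, key):
        return self.slice(key)

    def transpose(self) -> "Tensor":
        """2-D transpose."""

        def backward(out):
            self._accum(out.grad.T)

        return Tensor(self.data.T, parents=(self,), backward=backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(out):
            self._accum(out.grad.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._ensure_grad()
            self.grad += g  # broadcasts over the summed axes

        return Tensor(out_data, parents=(self,), backward=backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def softmax(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``mask`` (broadcastable, 1 = keep) removes
    masked positions from the normalization."""
    z = x.data
    if mask is not None:
        z = np.where(mask, z, -np.inf)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def backward(out):
        g = out.grad
        dot = (g * out.data).sum(axis=-1, keepdims=True)
        x._accum(out.data * (g - dot))

    return Tensor(out_data, parents=(x,), backward=backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out_data = weight.data[ids]

    def backward(out):
        g = weight._ensure_grad()
        np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, weight.data.shape[-1]))

    return Tensor(out_data, parents=(weight,), backward=backward)


def index_time(x: Tensor, idx: np.ndarray) -> Tensor:
    """Per-row time gather: ``out[b, t] = x[b, idx[b, t]]`` for (B, T, H)."""
    B = x.data.shape[0]
    rows = np.arange(B)[:, None]
    out_data = x.data[rows, idx]

    def backward(out):
        np.add.at(x._ensure_grad(), (rows, idx), out.grad)

    return Tensor(out_data, parents=(x,), backward=backward)


def lstm_cell(gates: Tensor, c_prev: Tensor) -> Tensor:
    """Fused LSTM cell: pre-activation gates (B, 4H) + previous cell state
    (B, H) → concatenated ``[h, c]`` (B, 2H).

    Gate order is input, forget, update, output.  Returning the pair as one
    array keeps the unrolled graph small; callers slice ``[:, :H]`` for h
    and ``[:, H:]`` for c.
    """
    B, four_h = gates.data.shape
    H = four_h // 4
    g = gates.data
    i = 1.0 / (1.0 + np.exp(-g[:, :H]))
    f = 1.0 / (1.0 + np.exp(-g[:, H:2 * H]))
    u = np.tanh(g[:, 2 * H:3 * H])
    o = 1.0 / (1.0 + np.exp(-g[:, 3 * H:]))
    c = f * c_prev.data + i * u
    tc = np.tanh(c)
    h = o * tc
    out_data = np.concatenate([h, c], axis=1)

    def backward(out):
        dh = out.grad[:, :H]
        dc = out.grad[:, H:] + dh * o * (1.0 - tc * tc)
        dg = np.empty_like(g)
        dg[:, :H] = dc * u * i * (1.0 - i)
        dg[:, H:2 * H] = dc * c_prev.data * f * (1.0 - f)
        dg[:, 2 * H:3 * H] = dc * i * (1.0 - u * u)
        dg[:, 3 * H:] = dh * tc * o * (1.0 - o)
        gates._accum(dg)
        if c_prev.requires_grad:
            c_prev._accum(dc * f)

    return Tensor(out_data, parents=(gates, c_prev), backward=backward)


def cross_entropy_sum(logits: Tensor, targets: np.ndarray,
                      mask: np.ndarray) -> Tensor:
    """Sum of masked token negative log-likelihoods.

    ``logits`` is (B, V); ``targets`` (B,) integer classes; ``mask`` (B,)
    with 1 on real tokens and 0 on padding.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    sez = ez.sum(axis=-1)
    logp = z[np.arange(len(targets)), targets] - np.log(sez)
    out_data = -(logp * mask).sum()

    def backward(out):
        p = ez / sez[:, None]
        p[np.arange(len(targets)), targets] -= 1.0
        logits._accum(out.grad * p * mask[:, None])

    return Tensor(out_data, parents=(logits,), backward=backward)
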