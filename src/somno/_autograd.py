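"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the package's networks need: broadcasted
arithmetic, matmul (batched), exp/log/tanh/sigmoid/ELU, reductions, reshapes,
indexing, concatenation and a strided 1-D convolution primitive. Gradients are
accumulated by iterative topological traversal, so graphs thousands of nodes
deep (recurrent unrolls) do not hit the recursion limit.

Every tensor op checks a module-level ``grad_enabled`` flag; inside
``no_grad()`` no graph is built, which keeps pure inference cheap.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float32


@contextlib.contextmanager
def no_grad():
    """Disable graph construction within the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def get_dtype():
    return _DTYPE


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily change the working float dtype (e.g. float64 for
    finite-difference gradient checks)."""
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DTYPE) if x.dtype != _DTYPE else x
    return np.asarray(x, dtype=_DTYPE)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=self.data.dtype)
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        """Accumulate a gradient array the caller guarantees is freshly
        allocated and unaliased, allowing ownership transfer."""
        if self.grad is None and g.shape == self.data.shape and g.dtype == self.data.dtype:
            self.grad = g
        else:
            self._accumulate(g)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # intermediate grads are never read again; freeing them both
                # caps memory and lets closures transfer ownership of views
                node.grad = None

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate_owned(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate_owned(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate_owned(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate_owned(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate_owned(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        out_data = np.where(neg, alpha * np.expm1(self.data), self.data)
        deriv = np.where(neg, out_data + alpha, np.asarray(1.0, dtype=out_data.dtype))

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * deriv)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Plain-array max, used for numerically stable softmax/logsumexp."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        return out if keepdims else out.squeeze(axis)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), backward)

    def squeeze(self, axis: int):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(np.squeeze(self.data, axis=axis), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    # -- misc -------------------------------------------------------------

    def masked_fill(self, mask: np.ndarray, value: float):
        """Set entries where ``mask`` is True to ``value`` (no grad there)."""
        out_data = np.where(mask, value, self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate_owned(np.where(mask, 0.0, g))

        return Tensor._make(out_data, (self,), backward)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


# -- 1-D convolution primitive --------------------------------------------


def _im2col1d(x: np.ndarray, kernel: int, stride: int, padding: int):
    """(N, C, L) -> strided view (N, C, K, L_out); caller copies via reshape."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    n, c, l = x.shape
    l_out = (l - kernel) // stride + 1
    s0, s1, s2 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, kernel, l_out), strides=(s0, s1, s2, s2 * stride)
    )
    return cols, l_out


def conv1d_cl(x: Tensor, weight: Tensor, bias: Tensor, stride: int, padding: int) -> Tensor:
    """Channels-last strided 1-D convolution.

    x (N, L, Cin), weight (K*Cin, Cout) -> (N, L_out, Cout). The layout keeps
    both the im2col copy and the output gemm contiguous, with no transposes.
    """
    n, l, c_in = x.data.shape
    kc, c_out = weight.data.shape
    k = kc // c_in
    l_out = (l + 2 * padding - k) // stride + 1

    def _tap_range(kk):
        # output positions j whose tap kk reads inside [0, l)
        off = kk - padding
        j0 = max(0, (-off + stride - 1) // stride)
        j1 = min(l_out, (l - 1 - off) // stride + 1)
        return j0, j1, off

    def _cols():
        cols = np.zeros((n, l_out, k, c_in), dtype=x.data.dtype)
        for kk in range(k):
            j0, j1, off = _tap_range(kk)
            if j1 > j0:
                lo = off + j0 * stride
                hi = off + (j1 - 1) * stride + 1
                cols[:, j0:j1, kk, :] = x.data[:, lo:hi:stride, :]
        return cols.reshape(n * l_out, kc)

    cols = _cols()
    out_data = (cols @ weight.data + bias.data).reshape(n, l_out, c_out)
    cache = cols if _GRAD_ENABLED and weight.requires_grad else None

    def backward(g):
        g2 = np.ascontiguousarray(g).reshape(n * l_out, c_out)
        if weight.requires_grad:
            weight._accumulate_owned(cache.T @ g2)
        if bias.requires_grad:
            bias._accumulate_owned(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ weight.data.T).reshape(n, l_out, k, c_in)
            gx = np.zeros((n, l, c_in), dtype=g.dtype)
            for kk in range(k):
                j0, j1, off = _tap_range(kk)
                if j1 > j0:
                    lo = off + j0 * stride
                    hi = off + (j1 - 1) * stride + 1
                    gx[:, lo:hi:stride, :] += gcols[:, j0:j1, kk, :]
            x._accumulate_owned(gx)

    return Tensor._make(out_data, (x, weight, bias), backward)


# -- fused normalization primitives ----------------------------------------


def _norm_fused(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
                eps: float, bshape) -> Tensor:
    """y = gamma * (x - mean) / sqrt(var + eps) + beta, reduced over ``axes``.

    Single graph node with the standard closed-form normalization backward;
    only the normalized activations are retained.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd
    out_data = xhat * gamma.data.reshape(bshape) + beta.data.reshape(bshape)
    n_red = int(np.prod([x.data.shape[a] for a in axes]))
    # gamma/beta gradients reduce over every broadcast (size-1) axis
    param_axes = tuple(i for i, s in enumerate(gamma.data.reshape(bshape).shape) if s == 1)

    def backward(g):
        gx = g * xhat
        if gamma.requires_grad:
            gamma._accumulate(gx.sum(axis=param_axes).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=param_axes).reshape(beta.data.shape))
        if x.requires_grad:
            gb = gamma.data.reshape(bshape)
            s1 = (g.sum(axis=axes, keepdims=True) * gb) / n_red
            s2 = (gx.sum(axis=axes, keepdims=True) * gb) / n_red
            # dx = invstd * (g*gamma - s1 - xhat*s2), built with in-place ops
            dx = np.multiply(xhat, -s2)
            dx -= s1
            tmp = g * gb
            dx += tmp
            dx *= invstd
            x._accumulate(dx)

    return Tensor._make(out_data, (x, gamma, beta), backward)


# -- gradient checkpointing -------------------------------------------------


def checkpoint_map(fn, x: Tensor, chunk: int, params: list[Tensor]) -> Tensor:
    """Apply ``fn`` over leading-axis chunks of ``x`` with recomputation.

    The forward pass runs without building a graph; during backward each
    chunk's subgraph is rebuilt and backpropagated, so peak memory scales
    with the chunk size instead of the full input. ``params`` lists the
    trainable tensors ``fn`` closes over (for graph connectivity). ``fn``
    must be deterministic given its inputs (no dropout inside).
    """
    with no_grad():
        outs = [fn(Tensor(x.data[i : i + chunk])) for i in range(0, x.data.shape[0], chunk)]
    out_data = np.concatenate([o.data for o in outs], axis=0)
    del outs

    if not _GRAD_ENABLED:
        return Tensor(out_data)

    def backward(g):
        offset = 0
        gx_parts = []
        for i in range(0, x.data.shape[0], chunk):
            xin = Tensor(x.data[i : i + chunk], requires_grad=True)
            out = fn(xin)
            n_i = out.data.shape[0]
            out.backward(g[offset : offset + n_i])
            offset += n_i
            if x.requires_grad:
                gx_parts.append(xin.grad)
        if x.requires_grad:
            x._accumulate(np.concatenate(gx_parts, axis=0))

    return Tensor._make(out_data, (x, *params), backward)
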