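"""Neural-network layers and optimization on top of the autodiff engine.

Layer semantics follow the conventions of mainstream deep-learning libraries
(post-norm transformer encoder blocks, inverted dropout, Kaiming/Xavier-style
fan-based initialization) so that the architecture descriptions in the docs
read the way practitioners expect.
"""

from __future__ import annotations

import math

import numpy as np

from . import _fastops
from ._autograd import (
    Tensor,
    _norm_fused,
    concatenate,
    conv1d_cl,
    get_dtype,
    grad_enabled,
)

__all__ = [
    "Module",
    "Linear",
    "FusedConvBlock",
    "BatchNorm1d",
    "LayerNorm",
    "Dropout",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "BiLSTM",
    "AttentionPool",
    "sinusoidal_encoding",
    "Adam",
    "clip_grad_norm",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data.copy() for k, v in self._params.items()}
        out.update({prefix + k: v.copy() for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, v in self._params.items():
            v.data = np.asarray(state[prefix + k], dtype=get_dtype()).copy()
        for k in self._buffers:
            self._buffers[k] = np.asarray(state[prefix + k]).copy()
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / math.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (in_features, out_features), in_features)
        self.has_bias = bias
        if bias:
            self.bias = _param(rng, (out_features,), in_features)

    def forward(self, x: Tensor) -> Tensor:
        # flatten leading axes so the weight gradient is one gemm rather
        # than a batched outer-product stack
        lead = x.data.shape[:-1]
        if len(lead) > 1:
            x = x.reshape(int(np.prod(lead)), x.data.shape[-1])
        out = x @ self.weight
        if self.has_bias:
            out = out + self.bias
        if len(lead) > 1:
            out = out.reshape(*lead, out.data.shape[-1])
        return out


class BatchNorm1d(Module):
    """Per-feature-map normalization over (N, L); input shape (N, C, L)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(num_features)
        self._buffers["running_var"] = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            if grad_enabled():  # skip during checkpoint recomputation passes
                mu = x.data.mean(axis=(0, 2))
                n = x.data.shape[0] * x.data.shape[2]
                unbiased = x.data.var(axis=(0, 2)) * (n / max(n - 1, 1))
                m = self.momentum
                self._buffers["running_mean"] = (
                    (1 - m) * self._buffers["running_mean"] + m * mu
                )
                self._buffers["running_var"] = (
                    (1 - m) * self._buffers["running_var"] + m * unbiased
                )
            return _norm_fused(x, self.gamma, self.beta, (0, 2), self.eps, (1, -1, 1))
        mu = Tensor(self._buffers["running_mean"][None, :, None])
        var = Tensor(self._buffers["running_var"][None, :, None])
        xhat = (x - mu) / ((var + Tensor(self.eps)) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        bshape = (1,) * (x.data.ndim - 1) + (-1,)
        return _norm_fused(x, self.gamma, self.beta, (x.data.ndim - 1,), self.eps, bshape)


class FusedConvBlock(Module):
    """Channels-last Conv1d -> BatchNorm -> ELU -> LayerNorm, fused.

    When float32 activations are in use, the normalization/activation tail
    runs through single-pass compiled kernels with an analytic backward;
    in float64 (gradient-check) mode it falls back to composed autograd ops,
    so the fused path can be validated against the reference path.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 2, padding: int = 1, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.stride, self.padding, self.kernel = stride, padding, kernel
        self.eps, self.momentum = eps, momentum
        fan_in = in_ch * kernel
        self.weight = _param(rng, (kernel * in_ch, out_ch), fan_in)
        self.bias = _param(rng, (out_ch,), fan_in)
        self.bn_gamma = Tensor(np.ones(out_ch), requires_grad=True)
        self.bn_beta = Tensor(np.zeros(out_ch), requires_grad=True)
        self.ln_gamma = Tensor(np.ones(out_ch), requires_grad=True)
        self.ln_beta = Tensor(np.zeros(out_ch), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(out_ch)
        self._buffers["running_var"] = np.ones(out_ch)

    def _tail_reference(self, y: Tensor, mean: Tensor, var: Tensor) -> Tensor:
        xhat = (y - mean) / ((var + Tensor(self.eps)) ** 0.5)
        z = (xhat * self.bn_gamma + self.bn_beta).elu()
        return _norm_fused(z, self.ln_gamma, self.ln_beta, (z.data.ndim - 1,),
                           self.eps, (1,) * (z.data.ndim - 1) + (-1,))

    def forward(self, x: Tensor) -> Tensor:
        y = conv1d_cl(x, self.weight, self.bias, self.stride, self.padding)
        n, l_out, c = y.data.shape
        if self.training:
            y2 = y.reshape(n * l_out, c)
            mean, var = _fastops.bn_stats(y2.data)
            if grad_enabled():
                m_ = self.momentum
                nn_ = n * l_out
                unbiased = var * (nn_ / max(nn_ - 1, 1))
                self._buffers["running_mean"] = (
                    (1 - m_) * self._buffers["running_mean"] + m_ * mean
                )
                self._buffers["running_var"] = (
                    (1 - m_) * self._buffers["running_var"] + m_ * unbiased
                )
        else:
            mean = self._buffers["running_mean"].astype(y.data.dtype)
            var = self._buffers["running_var"].astype(y.data.dtype)

        if get_dtype() is not np.float32:
            # reference path (used by equivalence and FD tests)
            mean_t = Tensor(mean.reshape(1, -1))
            var_t = Tensor(var.reshape(1, -1))
            if self.training:
                mu = y.reshape(n * l_out, c).mean(axis=0, keepdims=True)
                var_g = ((y.reshape(n * l_out, c) - mu) ** 2).mean(axis=0, keepdims=True)
                out = self._tail_reference(y.reshape(n * l_out, c), mu, var_g)
            else:
                out = self._tail_reference(y.reshape(n * l_out, c), mean_t, var_t)
            return out.reshape(n, l_out, c)

        istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = mean.astype(np.float32)
        y2 = y.reshape(n * l_out, c)
        g1, b1 = self.bn_gamma, self.bn_beta
        g2, b2 = self.ln_gamma, self.ln_beta
        if not self.training:
            out_data = _fastops.norm_act_norm_eval(
                y2.data, mean, istd, g1.data, b1.data, g2.data, b2.data,
                np.float32(self.eps))
            return Tensor(out_data).reshape(n, l_out, c)

        out_data, bn_xhat, zs, ln_mean, ln_istd = _fastops.fused_norm_act_norm_fwd(
            y2.data, mean, istd, g1.data, b1.data, g2.data, b2.data,
            np.float32(self.eps))

        def backward(g):
            gx, dg1, db1, dg2, db2 = _fastops.fused_norm_act_norm_bwd(
                np.ascontiguousarray(g), bn_xhat, zs, istd, g1.data,
                g2.data, ln_mean, ln_istd)
            if g1.requires_grad:
                g1._accumulate_owned(dg1)
            if b1.requires_grad:
                b1._accumulate_owned(db1)
            if g2.requires_grad:
                g2._accumulate_owned(dg2)
            if b2.requires_grad:
                b2._accumulate_owned(db2)
            if y2.requires_grad:
                y2._accumulate_owned(gx)

        out = Tensor._make(out_data, (y2, g1, b1, g2, b2), backward)
        return out.reshape(n, l_out, c)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.data.shape, dtype=np.float32) >= self.p).astype(
            get_dtype()) * get_dtype()(1.0 / (1.0 - self.p))
        return x * Tensor(keep)


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention with an optional padding mask.

    ``key_padding_mask`` is a boolean array of shape (B, S) with True marking
    VALID positions; invalid keys receive -inf scores before the softmax.
    """

    def __init__(self, rng, dim: int, n_heads: int):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.qkv = Linear(rng, dim, 3 * dim)
        self.out = Linear(rng, dim, dim)

    def forward(self, x: Tensor, key_padding_mask: np.ndarray | None = None) -> Tensor:
        b, s, d = x.data.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (B, S, 3D)
        qkv = qkv.reshape(b, s, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3, B, H, S, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(hd))  # (B, H, S, S)
        if key_padding_mask is not None:
            invalid = ~key_padding_mask[:, None, None, :]  # (B, 1, 1, S)
            scores = scores.masked_fill(np.broadcast_to(invalid, scores.shape), -1e30)
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (B, H, S, hd)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, s, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention and feed-forward sublayers with
    residual connections, each followed by layer normalization."""

    def __init__(self, rng, dim: int, n_heads: int, ffn_width: int, dropout: float):
        super().__init__()
        self.attn = MultiheadSelfAttention(rng, dim, n_heads)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, ffn_width)
        self.ff2 = Linear(rng, ffn_width, dim)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, key_padding_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, key_padding_mask)))
        x = self.norm2(x + self.drop(self.ff2(self.drop(self.ff1(x).relu()))))
        return x


class _LSTMCellStack(Module):
    """One direction of one LSTM layer; gates fused into two matmuls."""

    def __init__(self, rng, input_size: int, hidden_size: int):
        super().__init__()
        self.hidden = hidden_size
        self.w_ih = _param(rng, (input_size, 4 * hidden_size), hidden_size)
        self.w_hh = _param(rng, (hidden_size, 4 * hidden_size), hidden_size)
        self.b = _param(rng, (4 * hidden_size,), hidden_size)

    def forward(self, xs: Tensor, reverse: bool = False) -> Tensor:
        """xs: (B, S, In) -> (B, S, H), zero initial state."""
        b, s, _ = xs.data.shape
        hsz = self.hidden
        h = Tensor(np.zeros((b, hsz)))
        c = Tensor(np.zeros((b, hsz)))
        order = range(s - 1, -1, -1) if reverse else range(s)
        outs: list[Tensor | None] = [None] * s
        x_proj = xs @ self.w_ih + self.b  # precompute input contributions
        for t in order:
            gates = x_proj[:, t, :] + h @ self.w_hh
            i = gates[:, :hsz].sigmoid()
            f = gates[:, hsz : 2 * hsz].sigmoid()
            g = gates[:, 2 * hsz : 3 * hsz].tanh()
            o = gates[:, 3 * hsz :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h.reshape(b, 1, hsz)
        return concatenate(outs, axis=1)


class BiLSTM(Module):
    """Stacked bidirectional LSTM; per-timestep output dim = 2 * hidden."""

    def __init__(self, rng, input_size: int, hidden_size: int, n_layers: int = 2):
        super().__init__()
        self.layers_fwd: list[_LSTMCellStack] = []
        self.layers_bwd: list[_LSTMCellStack] = []
        for li in range(n_layers):
            in_sz = input_size if li == 0 else 2 * hidden_size
            fwd = _LSTMCellStack(rng, in_sz, hidden_size)
            bwd = _LSTMCellStack(rng, in_sz, hidden_size)
            setattr(self, f"fwd{li}", fwd)
            setattr(self, f"bwd{li}", bwd)
            self.layers_fwd.append(fwd)
            self.layers_bwd.append(bwd)

    def forward(self, x: Tensor) -> Tensor:
        for fwd, bwd in zip(self.layers_fwd, self.layers_bwd):
            x = concatenate([fwd(x), bwd(x, reverse=True)], axis=-1)
        return x


class AttentionPool(Module):
    """Learned-query attention pooling over one axis.

    Produces non-negative weights summing to one over valid positions and
    returns the weighted average. Input (B, S, D) -> output (B, D).
    """

    def __init__(self, rng, dim: int):
        super().__init__()
        self.query = _param(rng, (dim,), dim)
        self.key = Linear(rng, dim, dim)

    def weights(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        scores = (self.key(x) @ self.query.reshape(-1, 1)).squeeze(-1)  # (B, S)
        scores = scores * (1.0 / math.sqrt(self.query.data.size))
        if mask is not None:
            scores = scores.masked_fill(~mask, -1e30)
        return scores.softmax(axis=-1)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        w = self.weights(x, mask)  # (B, S)
        return (x * w.reshape(*w.data.shape, 1)).sum(axis=-2)


def sinusoidal_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Standard sine/cosine positional encoding table, shape (S, D)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / dim)
    enc = np.zeros((n_positions, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    total = math.sqrt(
        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
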