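"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, softmax
from . import tensor as _tensor_mod

__all__ = [
    "Module",
    "ModuleList",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "FeedForward",
    "TransformerBlock",
    "Conv2d",
    "set_rng",
    "get_rng",
]

# Ambient generator used by stochastic layers (dropout). Training code seeds
# it explicitly; `set_rng` makes every forward pass reproducible.
_RNG = np.random.default_rng(0)


def set_rng(seed_or_rng) -> None:
    global _RNG
    if isinstance(seed_or_rng, np.random.Generator):
        _RNG = seed_or_rng
    else:
        _RNG = np.random.default_rng(int(seed_or_rng))


def get_rng() -> np.random.Generator:
    return _RNG


class Module:
    """Base class: tracks parameters/submodules via attribute inspection."""

    training: bool = False

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, ModuleList):
                for sub in value:
                    yield from sub.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()


class ModuleList(list):
    pass


def _init(rng, shape, scale, dtype):
    return Tensor((rng.standard_normal(shape) * scale).astype(dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng=None, bias: bool = True, dtype=np.float32):
        rng = rng or get_rng()
        self.weight = _init(rng, (in_dim, out_dim), 1.0 / np.sqrt(in_dim), dtype)
        self.bias = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng=None, dtype=np.float32):
        rng = rng or get_rng()
        self.weight = _init(rng, (n, dim), 0.02, dtype)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (get_rng().random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * mask


class MultiHeadAttention(Module):
    """Scaled dot-product attention; query and key/value sources may differ."""

    def __init__(self, dim: int, heads: int, rng=None, dtype=np.float32):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng, dtype=dtype)
        self.wk = Linear(dim, dim, rng, dtype=dtype)
        self.wv = Linear(dim, dim, rng, dtype=dtype)
        self.wo = Linear(dim, dim, rng, dtype=dtype)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, kv: Tensor | None = None) -> Tensor:
        kv = query if kv is None else kv
        B, Tq, D = query.shape
        Tk = kv.shape[1]
        q = self._split(self.wq(query), B, Tq)
        k = self._split(self.wk(kv), B, Tk)
        v = self._split(self.wv(kv), B, Tk)
        att = softmax(q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.head_dim), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng=None, dtype=np.float32):
        self.fc1 = Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (attention + FFN, residual)."""

    def __init__(self, dim: int, heads: int, ffn_hidden: int | None = None, rng=None, dtype=np.float32):
        ffn_hidden = ffn_hidden or 4 * dim
        self.norm1 = LayerNorm(dim, dtype=dtype)
        self.attn = MultiHeadAttention(dim, heads, rng, dtype=dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)
        self.ffn = FeedForward(dim, ffn_hidden, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))


class Conv2d(Module):
    """2-D convolution (stride 1) as an im2col gather plus one matmul.

    Kernels here are small — e.g. (7, 5) over the gene-token map — so the
    window gather stays cheap relative to the matmul.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple, padding: tuple = (0, 0),
                 rng=None, dtype=np.float32):
        kh, kw = kernel
        if kh <= 0 or kw <= 0:
            raise ValueError(f"kernel dims must be positive, got {kernel}")
        rng = rng or get_rng()
        self.kernel = (kh, kw)
        self.padding = tuple(padding)
        scale = 1.0 / np.sqrt(in_ch * kh * kw)
        # weight[i, j] is an (in_ch, out_ch) matrix for kernel offset (i, j)
        self.weight = _init(rng, (kh, kw, in_ch, out_ch), scale, dtype)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        kh, kw = self.kernel
        ph, pw = self.padding
        if H + 2 * ph < kh or W + 2 * pw < kw:
            raise ValueError(f"input {H}x{W} too small for kernel {self.kernel} with padding {self.padding}")
        xp = _pad_through(x, (ph, pw)) if (ph or pw) else x
        Ho = H + 2 * ph - kh + 1
        Wo = W + 2 * pw - kw + 1
        # im2col: one (B, Ho, Wo, kh*kw*C) gather, then a single matmul
        cols = _im2col(xp, kh, kw)
        out = cols @ self.weight.reshape(kh * kw * C, -1) + self.bias
        return out.transpose(0, 3, 1, 2)


def _im2col(x: Tensor, kh: int, kw: int) -> Tensor:
    """(B, C, H, W) -> (B, Ho, Wo, kh*kw*C) sliding windows, differentiable."""
    B, C, H, W = x.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    data = np.ascontiguousarray(windows.transpose(0, 2, 3, 4, 5, 1)).reshape(B, Ho, Wo, kh * kw * C)
    out = Tensor(data)
    if _tensor_mod._GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            g = g.reshape(B, Ho, Wo, kh, kw, C)
            full = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    full[:, :, i:i + Ho, j:j + Wo] += g[:, :, :, i, j, :].transpose(0, 3, 1, 2)
            x._accum(full)

        out._backward = backward
    return out


def _pad_through(x: Tensor, pad: tuple) -> Tensor:
    ph, pw = pad
    B, C, H, W = x.shape
    data = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = Tensor(data)
    if _tensor_mod._GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            x._accum(g[:, :, ph:H + ph, pw:W + pw])

        out._backward = backward
    return out
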