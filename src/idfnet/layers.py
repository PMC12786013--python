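"""Neural-network building blocks on top of :mod:`idfnet.autograd`.

Modules follow the usual container pattern: a :class:`Module` owns named
parameters and sub-modules, exposes ``parameters()`` / ``state_dict()`` /
``load_state_dict()``, and a ``train`` flag that controls dropout.
Initialisation draws from an explicit ``numpy.random.Generator`` so whole
models are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "global_average_pool",
]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_training(self, mode: bool):
        self.training = mode
        for m in self._modules.values():
            m.set_training(mode)
        return self


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, n_in, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _im2col_indices(C, H, W, k, stride, pad):
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    i0 = np.repeat(np.arange(k), k)
    i0 = np.tile(i0, C)
    i1 = stride * np.repeat(np.arange(Ho), Wo)
    j0 = np.tile(np.arange(k), k * C)
    j1 = stride * np.tile(np.arange(Wo), Ho)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    c = np.repeat(np.arange(C), k * k).reshape(-1, 1)
    return c, i, j, Ho, Wo


class Conv2d(Module):
    """2-D convolution (NCHW) via im2col; supports stride and zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 1,
    ):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        c_out = self.weight.shape[0]
        w_flat = self.weight.reshape(c_out, -1)

        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        cols = np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3)).reshape(
            N, C * k * k, Ho * Wo
        )

        cols_t = Tensor(cols, requires_grad=x.requires_grad)

        def col_backward(g):
            # g: (N, C*k*k, Ho*Wo); scatter back one kernel offset at a time
            gk = g.reshape(N, C, k, k, Ho, Wo)
            gxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    gxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += gk[
                        :, :, ki, kj
                    ]
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            return (gxp,)

        if cols_t.requires_grad:
            cols_t._parents = (x,)
            cols_t._backward = col_backward

        out = w_flat @ cols_t  # (c_out, C*k*k) @ (N, C*k*k, L) -> (N, c_out, L)
        out = out + self.bias.reshape(1, c_out, 1)
        return out.reshape(N, c_out, Ho, Wo)


def global_average_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gain + self.shift


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Bidirectional multi-head self-attention over a short token sequence.

    Input/output: (N, T, D).  Every token attends to all tokens; attention
    rows are softmax-normalised. ``last_attention`` keeps the most recent
    attention weights (N, heads, T, T) for inspection.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"head count {n_heads} must divide model width {dim}")
        self.dim, self.n_heads, self.d_head = dim, n_heads, dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        N, T, D = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(N, T, h, dh).transpose(0, 2, 1, 3)  # (N,h,T,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data.copy()
        ctx = attn @ v  # (N,h,T,dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(N, T, D)
        return self.wo(ctx)


def concat_tokens(tokens: list[Tensor]) -> Tensor:
    """Stack per-modality (N, D) vectors into a (N, T, D) token sequence."""
    return concatenate([t.reshape(t.shape[0], 1, t.shape[1]) for t in tokens], axis=1)
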