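"""Neural-network building blocks over the autograd tensor.

Conv3d lowers to one of two schemes: small problems use an im2col gather
(numba-compiled) followed by a single BLAS matmul; large problems use a
kernel-offset loop of matmuls, which bounds memory at one padded copy of
the input instead of a k^3-inflated column buffer.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernels import gather_cols, scatter_add_cols
from .tensor import Tensor, concat, stack

__all__ = [
    "Parameter", "Module", "Linear", "Conv3d", "BatchNorm3d", "BiLSTM",
    "MultiheadAttention", "conv3d", "upsample_nearest", "Sequential",
    "ReLU", "GELU",
]


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters track grads even under no_grad creation


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        t, h, w = v
        return int(t), int(h), int(w)
    return int(v), int(v), int(v)


# ---------------------------------------------------------------------------
# functional primitives

_IDX_CACHE: dict[tuple, np.ndarray] = {}


def _gather_indices(padded, kernel, dilation, stride, out) -> np.ndarray:
    """Flat im2col gather indices of shape (k^3, P), cached per geometry."""
    key = (padded, kernel, dilation, stride, out)
    idx = _IDX_CACHE.get(key)
    if idx is None:
        (Tp, Hp, Wp), (kt, kh, kw) = padded, kernel
        (dt, dh, dw), (st, sh, sw), (ot, oh, ow) = dilation, stride, out
        t = (np.arange(kt) * dt)[:, None, None, None, None, None] \
            + (np.arange(ot) * st)[None, None, None, :, None, None]
        h = (np.arange(kh) * dh)[None, :, None, None, None, None] \
            + (np.arange(oh) * sh)[None, None, None, None, :, None]
        wi = (np.arange(kw) * dw)[None, None, :, None, None, None] \
            + (np.arange(ow) * sw)[None, None, None, None, None, :]
        idx = ((t * Hp + h) * Wp + wi).reshape(kt * kh * kw, ot * oh * ow)
        if len(_IDX_CACHE) > 256:
            _IDX_CACHE.clear()
        _IDX_CACHE[key] = idx
    return idx


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0, dilation=1) -> Tensor:
    """3-D convolution (cross-correlation), NCTHW layout.

    x: (N, C, T, H, W); w: (O, C, kt, kh, kw); b: (O,).
    """
    st, sh, sw = _triple(stride)
    pt, ph, pw = _triple(padding)
    dt, dh, dw = _triple(dilation)
    N, C, T, H, W = x.shape
    O, Cw, kt, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Cw}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    ot = (T + 2 * pt - (kt - 1) * dt - 1) // st + 1
    oh = (H + 2 * ph - (kh - 1) * dh - 1) // sh + 1
    ow = (W + 2 * pw - (kw - 1) * dw - 1) // sw + 1
    P = ot * oh * ow

    def slices(it, ih, iw):
        return (slice(None), slice(None),
                slice(it * dt, it * dt + ot * st, st),
                slice(ih * dh, ih * dh + oh * sh, sh),
                slice(iw * dw, iw * dw + ow * sw, sw))

    parents = (x, w) if b is None else (x, w, b)
    w_flat = w.data.reshape(O, C * kt * kh * kw)
    # small problems: one gather + matmul; large: offset loop (one padded copy)
    use_im2col = N * C * kt * kh * kw * P <= 4e7
    Tp, Hp, Wp = xp.shape[2:]

    def flat_idx() -> np.ndarray:
        return _gather_indices((Tp, Hp, Wp), (kt, kh, kw), (dt, dh, dw),
                               (st, sh, sw), (ot, oh, ow)).reshape(-1)

    def im2col() -> np.ndarray:
        xf = xp.reshape(N, C, Tp * Hp * Wp)
        return gather_cols(xf, flat_idx()).reshape(N, C * kt * kh * kw, P)

    if use_im2col:
        cols = im2col()
        y = np.matmul(w_flat, cols)
    else:
        y = np.zeros((N, O, P), dtype=xp.dtype)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    xs = np.ascontiguousarray(
                        xp[slices(it, ih, iw)]).reshape(N, C, P)
                    y += np.matmul(w.data[:, :, it, ih, iw], xs)
    if b is not None:
        y += b.data[None, :, None]
    out_data = y.reshape(N, O, ot, oh, ow)

    def bwd(g):
        gf = g.reshape(N, O, P)
        if b is not None and b.requires_grad:
            b._accum(gf.sum(axis=(0, 2)))
        need_dx = x.requires_grad
        if use_im2col:
            if w.requires_grad:
                cols_b = im2col()
                dw_flat = np.matmul(gf, cols_b.transpose(0, 2, 1)).sum(axis=0)
                w._accum(dw_flat.reshape(w.shape))
            if need_dx:
                dcols = np.matmul(w_flat.T, gf).reshape(
                    N, C, kt * kh * kw * P)
                dxf = np.zeros((N, C, Tp * Hp * Wp), dtype=xp.dtype)
                scatter_add_cols(dcols, flat_idx(), dxf)
                dxp = dxf.reshape(N, C, Tp, Hp, Wp)
                x._accum(dxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])
            return
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    sl = slices(it, ih, iw)
                    if w.requires_grad:
                        xs = np.ascontiguousarray(xp[sl]).reshape(N, C, P)
                        dw[:, :, it, ih, iw] = np.matmul(
                            gf, xs.transpose(0, 2, 1)).sum(axis=0)
                    if need_dx:
                        wk = w.data[:, :, it, ih, iw]  # (O,C)
                        dxs = np.matmul(wk.T, gf)      # (N,C,P)
                        dxp[sl] += dxs.reshape(N, C, ot, oh, ow)
        if w.requires_grad:
            w._accum(dw)
        if need_dx:
            x._accum(dxp[:, :, pt:pt + T, ph:ph + H, pw:pw + W])

    return Tensor._make(out_data, parents, bwd)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalisation over axes (0, 2, 3, 4).

    Returns (out, batch_mean, batch_var); a single primitive with the
    closed-form backward keeps one normalised copy instead of the chain of
    elementwise temporaries the composed form would retain.
    """
    axes = (0,) + tuple(range(2, x.ndim))
    cshape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = (x.data - mu) * inv
    out_data = gamma.data.reshape(cshape) * xn + beta.data.reshape(cshape)

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xn).sum(axis=axes))
        if x.requires_grad:
            gg = gamma.data.reshape(cshape) * g
            dx = inv * (gg - gg.mean(axis=axes, keepdims=True)
                        - xn * (gg * xn).mean(axis=axes, keepdims=True))
            x._accum(dx)

    out = Tensor._make(out_data, (x, gamma, beta), bwd)
    return out, mu.reshape(-1), var.reshape(-1)


def upsample_nearest(x: Tensor, factor) -> Tensor:
    """Nearest-neighbour upsampling of a (N, C, T, H, W) tensor by integer factors."""
    ft, fh, fw = _triple(factor)
    N, C, T, H, W = x.shape
    d = x.data
    if ft > 1:
        d = np.repeat(d, ft, axis=2)
    if fh > 1:
        d = np.repeat(d, fh, axis=3)
    if fw > 1:
        d = np.repeat(d, fw, axis=4)

    def bwd(g):
        if x.requires_grad:
            gg = g.reshape(N, C, T, ft, H, fh, W, fw).sum(axis=(3, 5, 7))
            x._accum(gg)

    return Tensor._make(d, (x,), bwd)


# ---------------------------------------------------------------------------
# module system


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}"))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for mname, m in self._named_modules():
            for bname in getattr(m, "_buffers", ()):  # running stats
                key = f"{mname}.{bname}" if mname else bname
                state[key] = getattr(m, bname)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for mname, m in self._named_modules():
            for bname in getattr(m, "_buffers", ()):
                key = f"{mname}.{bname}" if mname else bname
                buffers[key] = (m, bname)
        for key, arr in state.items():
            if key in params:
                if params[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(arr, dtype=params[key].data.dtype).copy()
            elif key in buffers:
                m, bname = buffers[key]
                setattr(m, bname, np.asarray(arr).copy())

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, val in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Module):
                yield from val._named_modules(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{full}.{i}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = math.sqrt(1.0 / n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    def __init__(self, n_in: int, n_out: int, kernel, rng: np.random.Generator,
                 stride=1, padding=0, dilation=1, bias: bool = True):
        super().__init__()
        kt, kh, kw = _triple(kernel)
        fan_in = n_in * kt * kh * kw
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (n_out, n_in, kt, kh, kw)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation)


class BatchNorm3d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self.n_ch = n_ch

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.n_ch) + (1,) * (x.ndim - 2)
        if self.training:
            out, mu, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        # affine with frozen statistics; gamma/beta still receive gradients
        inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps).reshape(shape))
        mu = Tensor(self.running_mean.reshape(shape))
        return (x - mu) * inv * self.gamma.reshape(shape) \
            + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class _LSTMDirection(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(1.0 / hidden)
        self.wx = Parameter(rng.uniform(-bound, bound, (n_in, 4 * hidden)))
        self.wh = Parameter(rng.uniform(-bound, bound, (hidden, 4 * hidden)))
        self.b = Parameter(np.zeros(4 * hidden))
        self.hidden = hidden

    def forward(self, x: Tensor, reverse: bool = False) -> Tensor:
        N, T, _ = x.shape
        Hn = self.hidden
        h = Tensor(np.zeros((N, Hn), dtype=x.data.dtype))
        c = Tensor(np.zeros((N, Hn), dtype=x.data.dtype))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in steps:
            xt = x[:, t, :]
            z = xt @ self.wx + h @ self.wh + self.b
            i = z[:, :Hn].sigmoid()
            f = z[:, Hn:2 * Hn].sigmoid()
            g = z[:, 2 * Hn:3 * Hn].tanh()
            o = z[:, 3 * Hn:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        return stack(outs, axis=1)  # (N, T, H)


class BiLSTM(Module):
    """Single-layer bidirectional LSTM over (N, T, C) sequences."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMDirection(n_in, hidden, rng)
        self.bwd = _LSTMDirection(n_in, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=2)


class MultiheadAttention(Module):
    """Self-attention over (N, T, D) sequences."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, T, D = x.shape
        h, dh = self.n_heads, D // self.n_heads
        qkv = self.qkv(x)  # (N, T, 3D)
        q = qkv[:, :, :D].reshape(N, T, h, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, D:2 * D].reshape(N, T, h, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * D:].reshape(N, T, h, dh).transpose(0, 2, 1, 3)
        attn = ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))).softmax(-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, T, D)
        return self.proj(out)
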