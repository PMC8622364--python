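"""Minimal numpy neural-network layer library.

Implements exactly the primitives the tile classifiers need — 2-D
convolution (grouped/depthwise), batch normalisation, dense layers,
squeeze-excitation, swish/ReLU/sigmoid, global average pooling — each with
a hand-written backward pass, plus an Adam optimizer that respects
per-parameter freeze flags.  Data layout is NCHW float32 throughout
(float64 supported for numerical-gradient checks).

Backward passes accumulate gradients into ``Param.grad``; frozen
parameters still propagate input gradients (needed to reach trainable
batch-norm parameters deep in a frozen backbone) but the optimizer never
touches them, so frozen values stay bit-identical for the whole run.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "BatchNorm2d", "ReLU", "Swish", "Sigmoid",
    "GlobalAvgPool", "Dense", "SqueezeExcite", "Sequential", "MBConv",
    "Adam", "bce_loss_and_grad",
]


class Param:
    """A learnable tensor with gradient buffer and freeze flag."""

    def __init__(self, value: np.ndarray, name: str = "", trainable: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Module:
    """Base layer: forward caches what backward needs; backward returns dx."""

    def params(self) -> list[Param]:
        """All parameters of this module and submodules, depth-first."""
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (BN running statistics), keyed by position."""
        out = {}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"bn{i}.running_mean"] = m.running_mean
                out[f"bn{i}.running_var"] = m.running_var
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Conv2d(Module):
    """Grouped 2-D convolution, NCHW, symmetric zero padding.

    padding="same" keeps the spatial grid at ceil(dim/stride) for odd
    kernels; groups=cin gives a depthwise convolution.  Weight shape is
    (cout, cin // groups, k, k).
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: str | int = "same", groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None, name: str = "conv",
                 dtype=np.float32):
        if cin % groups or cout % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.groups = cin, cout, k, stride, groups
        self.pad = (k // 2) if padding == "same" else int(padding)
        fan_in = (cin // groups) * k * k
        self.w = Param(_he_init(rng, (cout, cin // groups, k, k), fan_in, dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b") if bias else None
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, wdt = x.shape
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # sliding windows: (n, c, ho, wo, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        g = self.groups
        cpg_in, cpg_out = self.cin // g, self.cout // g
        wv = self.w.value.reshape(g, cpg_out, cpg_in, k, k)
        wing = win.reshape(n, g, cpg_in, win.shape[2], win.shape[3], k, k)
        out = np.einsum("ngihwkl,goikl->ngohw", wing, wv, optimize=True)
        out = out.reshape(n, self.cout, win.shape[2], win.shape[3])
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        self._cache = (x.shape, wing)
        return out

    def backward(self, dy):
        x_shape, wing = self._cache
        n, c, h, wdt = x_shape
        p, s, k, g = self.pad, self.stride, self.k, self.groups
        cpg_in, cpg_out = self.cin // g, self.cout // g
        ho, wo = dy.shape[2], dy.shape[3]
        dyg = dy.reshape(n, g, cpg_out, ho, wo)
        dw = np.einsum("ngohw,ngihwkl->goikl", dyg, wing, optimize=True)
        if self.w.trainable:
            self.w.grad += dw.reshape(self.w.value.shape)
        if self.b is not None and self.b.trainable:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        # scatter gradient back through the windows
        wv = self.w.value.reshape(g, cpg_out, cpg_in, k, k)
        dwin = np.einsum("ngohw,goikl->ngihwkl", dyg, wv, optimize=True)
        dwin = dwin.reshape(n, self.cin, ho, wo, k, k)
        dxp = np.zeros((n, c, h + 2 * p, wdt + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dwin[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + wdt] if p else dxp

    @property
    def n_params(self) -> int:
        return self.w.size + (self.b.size if self.b is not None else 0)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with affine scale/offset.

    Training mode normalises with batch statistics and updates running
    mean/variance (exponential average, momentum 0.1); inference mode
    uses the running statistics, making prediction deterministic.
    Running statistics are buffers, never counted as trainable.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn", dtype=np.float32):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(np.ones(c, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        if self.gamma.trainable:
            self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        if self.beta.trainable:
            self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dy * g * inv[None, :, None, None]
        n, _, h, w = shape
        m = n * h * w
        dxhat = dy * g
        # standard batch-norm backward through batch mean/var
        dx = (inv[None, :, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        return dx


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Swish(Module):
    """x * sigmoid(x) (the activation EfficientNet uses)."""

    def forward(self, x, train=False):
        s = 1.0 / (1.0 + np.exp(-x))
        self._cache = (x, s)
        return x * s

    def backward(self, dy):
        x, s = self._cache
        return dy * (s + x * s * (1.0 - s))


class Sigmoid(Module):
    def forward(self, x, train=False):
        self._s = 1.0 / (1.0 + np.exp(-x))
        return self._s

    def backward(self, dy):
        return dy * self._s * (1.0 - self._s)


class GlobalAvgPool(Module):
    """NCHW -> NC mean over the spatial grid."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "fc",
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (cin, cout), cin, dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b") if bias else None
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.w.value
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, dy):
        if self.w.trainable:
            self.w.grad += self._x.T @ dy
        if self.b is not None and self.b.trainable:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class SqueezeExcite(Module):
    """Channel attention: GAP -> 1x1 reduce (swish) -> 1x1 expand (sigmoid) -> scale."""

    def __init__(self, c: int, c_se: int, rng=None, name="se", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.reduce = Conv2d(c, c_se, 1, bias=True, rng=rng, name=f"{name}.reduce", dtype=dtype)
        self.act = Swish()
        self.expand = Conv2d(c_se, c, 1, bias=True, rng=rng, name=f"{name}.expand", dtype=dtype)
        self.gate = Sigmoid()

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        s = x.mean(axis=(2, 3))[:, :, None, None]
        s = self.gate(self.expand(self.act(self.reduce(s, train), train), train), train)
        self._cache = (x, s)
        return x * s

    def backward(self, dy):
        x, s = self._cache
        dx_direct = dy * s
        ds = (dy * x).sum(axis=(2, 3), keepdims=True)
        ds = self.reduce.backward(self.act.backward(self.expand.backward(self.gate.backward(ds))))
        n, c, h, w = x.shape
        return dx_direct + np.broadcast_to(ds, x.shape) / (h * w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class MBConv(Module):
    """Mobile inverted bottleneck block with squeeze-excitation.

    expand (1x1, skipped when expand_ratio == 1) -> depthwise kxk ->
    SE -> project 1x1, each conv followed by BN; swish after expand and
    depthwise; identity skip when stride == 1 and cin == cout.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, expand_ratio: int,
                 se_ratio: float = 0.25, rng=None, name="mbconv", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        cmid = cin * expand_ratio
        self.has_expand = expand_ratio != 1
        if self.has_expand:
            self.expand_conv = Conv2d(cin, cmid, 1, rng=rng, name=f"{name}.expand", dtype=dtype)
            self.expand_bn = BatchNorm2d(cmid, name=f"{name}.expand_bn", dtype=dtype)
            self.expand_act = Swish()
        self.dw_conv = Conv2d(cmid, cmid, k, stride=stride, groups=cmid, rng=rng,
                              name=f"{name}.dw", dtype=dtype)
        self.dw_bn = BatchNorm2d(cmid, name=f"{name}.dw_bn", dtype=dtype)
        self.dw_act = Swish()
        c_se = max(1, int(cin * se_ratio))  # SE width from the *unexpanded* input
        self.se = SqueezeExcite(cmid, c_se, rng=rng, name=f"{name}.se", dtype=dtype)
        self.project_conv = Conv2d(cmid, cout, 1, rng=rng, name=f"{name}.project", dtype=dtype)
        self.project_bn = BatchNorm2d(cout, name=f"{name}.project_bn", dtype=dtype)
        self.skip = stride == 1 and cin == cout

    def forward(self, x, train=False):
        y = x
        if self.has_expand:
            y = self.expand_act(self.expand_bn(self.expand_conv(y, train), train), train)
        y = self.dw_act(self.dw_bn(self.dw_conv(y, train), train), train)
        y = self.se(y, train)
        y = self.project_bn(self.project_conv(y, train), train)
        return x + y if self.skip else y

    def backward(self, dy):
        d = self.project_conv.backward(self.project_bn.backward(dy))
        d = self.se.backward(d)
        d = self.dw_conv.backward(self.dw_bn.backward(self.dw_act.backward(d)))
        if self.has_expand:
            d = self.expand_conv.backward(self.expand_bn.backward(self.expand_act.backward(d)))
        return d + dy if self.skip else d


class Adam:
    """Adam with per-parameter first/second moment, updating trainable params only."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self, all_params: list[Param] | None = None):
        for p in (all_params if all_params is not None else self.params):
            p.grad[...] = 0.0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.value.dtype)


def bce_loss_and_grad(probs: np.ndarray, labels: np.ndarray,
                      clip: float = 1e-7) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on clipped probabilities.

    Returns (mean loss, gradient w.r.t. the pre-sigmoid logit), using the
    analytic sigmoid+BCE gradient (p - y)/n.  Probabilities are clipped to
    [clip, 1-clip] inside the loss so a saturated prediction never yields
    an infinite loss.
    """
    p = np.clip(probs, clip, 1.0 - clip)
    y = labels.astype(p.dtype)
    loss = float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))
    dlogit = (probs - y) / probs.shape[0]
    return loss, dlogit.astype(probs.dtype)
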