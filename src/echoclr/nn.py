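"""Minimal NumPy neural-network engine for 3D video CNNs.

Implements exactly the layers the video encoders need — 3D convolution
(im2col with a hand-written backward pass), batch normalization, ReLU,
linear maps, global average pooling — plus an Adam optimizer.  Everything
is float32, fully deterministic given the initialization RNG, and designed
for small-batch CPU training.

Layout convention: activations are ``(B, C, T, H, W)`` arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Linear",
    "GlobalAvgPool3d",
    "Sequential",
    "BasicBlock3d",
    "Adam",
    "he_init",
]

# Cap on the number of floats materialized by one im2col chunk; keeps peak
# memory modest when running the full-size encoder on 112x112x32 clips.
_CHUNK_BUDGET = 1 << 24


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state arrays (e.g. batchnorm running stats)."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(a) for a in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or 3-tuple, got {v!r}")
    return t


class Conv3d(Layer):
    """3D convolution over (B, C, T, H, W), stride and zero padding per axis."""

    def __init__(self, cin: int, cout: int, kernel, stride=1, padding=0,
                 rng: np.random.Generator | None = None, bias: bool = False):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        kt, kh, kw = self.kernel
        fan_in = cin * kt * kh * kw
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(he_init(rng, (cout, cin, kt, kh, kw), fan_in))
        self.bias = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_shape(self, xp_shape):
        _, _, tp, hp, wp = xp_shape
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        return ((tp - kt) // st + 1, (hp - kh) // sh + 1, (wp - kw) // sw + 1)

    def _pad(self, x):
        pt, ph, pw = self.padding
        if pt or ph or pw:
            return np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        return x

    def _windows(self, xp, t0, t1):
        """im2col matrix for output temporal rows t0:t1 -> (B*L, C*kt*kh*kw)."""
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        sub = xp[:, :, t0 * st: (t1 - 1) * st + kt]
        win = np.lib.stride_tricks.sliding_window_view(sub, (kt, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::st, ::sh, ::sw]  # (B,C,to,ho,wo,kt,kh,kw)
        b, c, to, ho, wo = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b * to * ho * wo, -1)
        return cols, (to, ho, wo)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = self._pad(x)
        b = x.shape[0]
        cout = self.weight.value.shape[0]
        to, ho, wo = self._out_shape(xp.shape)
        wmat = self.weight.value.reshape(cout, -1)
        y = np.empty((b, to, ho, wo, cout), dtype=np.float32)
        step = max(1, int(_CHUNK_BUDGET // max(1, b * ho * wo * wmat.shape[1])))
        for t0 in range(0, to, step):
            t1 = min(to, t0 + step)
            cols, (tc, _, _) = self._windows(xp, t0, t1)
            y[:, t0:t1] = (cols @ wmat.T).reshape(b, tc, ho, wo, cout)
        if self.bias is not None:
            y += self.bias.value
        y = np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))
        if train:
            self._cache = (xp, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        b, cout = dy.shape[:2]
        to, ho, wo = dy.shape[2:]
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self.padding
        wmat = self.weight.value.reshape(cout, -1)
        dy_mat_full = dy.transpose(0, 2, 3, 4, 1)  # (B,to,ho,wo,cout)

        # dW via recomputed im2col chunks
        dwmat = np.zeros_like(wmat)
        step = max(1, int(_CHUNK_BUDGET // max(1, b * ho * wo * wmat.shape[1])))
        for t0 in range(0, to, step):
            t1 = min(to, t0 + step)
            cols, _ = self._windows(xp, t0, t1)
            dwmat += dy_mat_full[:, t0:t1].reshape(-1, cout).T @ cols
        self.weight.grad += dwmat.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))

        # dx: scatter each kernel offset's contribution back onto the padded grid
        dxp = np.zeros_like(xp)
        w = self.weight.value
        for a in range(kt):
            for bb in range(kh):
                for cc in range(kw):
                    # (B,to,ho,wo,cout) x (cout,cin) -> (B,to,ho,wo,cin)
                    contrib = dy_mat_full @ w[:, :, a, bb, cc]
                    dxp[:, :, a: a + st * to: st, bb: bb + sh * ho: sh, cc: cc + sw * wo: sw] += \
                        contrib.transpose(0, 4, 1, 2, 3)
        _, _, t, h, wd = x_shape
        dx = dxp[:, :, pt: pt + t, ph: ph + h, pw: pw + wd]
        self._cache = None
        return np.ascontiguousarray(dx)


class BatchNorm3d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv)
        return (self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        n = dy.size / dy.shape[1]
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dy * g
        dx = (inv.reshape(shape) / n) * (
            n * dxhat
            - dxhat.sum(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(he_init(rng, (cout, cin), cin))
        self.bias = Param(np.zeros(cout, dtype=np.float32))
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx


class GlobalAvgPool3d(Layer):
    """(B, C, T, H, W) -> (B, C) mean over the spatiotemporal grid."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, t, h, w = self._shape
        scale = 1.0 / (t * h * w)
        return np.broadcast_to(
            (dy * scale)[:, :, None, None, None], self._shape
        ).astype(np.float32).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def buffers(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for l in self.layers:
            out.extend(l.buffers())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class BasicBlock3d(Layer):
    """Two 3x3x3 conv/BN units with an identity (or 1x1x1-projected) shortcut."""

    def __init__(self, cin: int, cout: int, stride=1, rng: np.random.Generator | None = None):
        s = _triple(stride)
        self.conv1 = Conv3d(cin, cout, 3, stride=s, padding=1, rng=rng)
        self.bn1 = BatchNorm3d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm3d(cout)
        self.relu2 = ReLU()
        if s != (1, 1, 1) or cin != cout:
            self.down_conv: Conv3d | None = Conv3d(cin, cout, 1, stride=s, rng=rng)
            self.down_bn: BatchNorm3d | None = BatchNorm3d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def params(self) -> list[Param]:
        ps = (self.conv1.params() + self.bn1.params()
              + self.conv2.params() + self.bn2.params())
        if self.down_conv is not None:
            ps += self.down_conv.params() + self.down_bn.params()
        return ps

    def buffers(self) -> list[np.ndarray]:
        bs = self.bn1.buffers() + self.bn2.buffers()
        if self.down_bn is not None:
            bs += self.down_bn.buffers()
        return bs

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.down_conv is not None:
            shortcut = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            shortcut = x
        return self.relu2.forward(out + shortcut, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dy)
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(
                self.conv2.backward(self.bn2.backward(dy))
            ))
        )
        if self.down_conv is not None:
            d_short = self.down_conv.backward(self.down_bn.backward(dy))
        else:
            d_short = dy
        return d_main + d_short


class Adam:
    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
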