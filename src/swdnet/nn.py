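"""Minimal numpy layer library with manual backpropagation.

Implements exactly the pieces the seizure-detection architectures need:
2-D convolution (im2col + GEMM), batch normalization, ReLU, max pooling,
residual blocks, per-frame dense layers, dropout, bidirectional GRU
(dual-bias / "reset-after" gate formulation) and the Adam optimizer.
Tensors are NHWC: (batch, frames, features, channels); sequence tensors
are (batch, frames, width). All parameters are float32.

Gradient correctness is enforced by finite-difference checks in the test
suite rather than by an autodiff framework.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2D", "BatchNorm", "ReLU", "MaxPool1x2",
    "ResidualBlock", "PlainConvBlock", "FrameFlatten", "FrameDense",
    "Dropout", "BiGRU", "Sigmoid", "Sequential", "Adam",
]

_DTYPE = np.float32


class Param:
    """A trainable array with its gradient and weight-decay eligibility."""

    __slots__ = ("name", "value", "grad", "l2")

    def __init__(self, name: str, value: np.ndarray, l2: bool = False):
        self.name = name
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.l2 = l2

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    name: str = ""
    activation: str = "-"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.params())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Convolutional layers
# ---------------------------------------------------------------------------

class Conv2D(Layer):
    """Same-padded stride-1 convolution, NHWC, kernel (kh, kw, cin, cout).

    3x3 convolutions are conventionally bias-free here (the following
    batch norm absorbs any offset); 1x1 projection convolutions carry a
    bias.
    """

    def __init__(self, cin: int, cout: int, ksize: tuple[int, int],
                 bias: bool, name: str, rng: np.random.Generator,
                 activation: str = "-"):
        self.name = name
        self.activation = activation
        kh, kw = ksize
        self.ksize = ksize
        self.cin, self.cout = cin, cout
        fan_in = kh * kw * cin
        w = rng.standard_normal((kh, kw, cin, cout)) * np.sqrt(2.0 / fan_in)
        self.w = Param(f"{name}.w", w, l2=True)
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def _pad(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.ksize
        ph, pw = kh // 2, kw // 2
        if ph == 0 and pw == 0:
            return x
        return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        self._x = x if training else None
        kh, kw = self.ksize
        if kh == 1 and kw == 1:
            out = x @ self.w.value[0, 0]
        else:
            xp = self._pad(x)
            view = sliding_window_view(xp, (kh, kw), axis=(1, 2))
            out = np.tensordot(view, self.w.value, axes=([3, 4, 5], [2, 0, 1]))
        if self.b is not None:
            out = out + self.b.value
        return out.astype(_DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward requires forward(training=True)"
        kh, kw = self.ksize
        dout = np.ascontiguousarray(dout, dtype=_DTYPE)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 1, 2))
        if kh == 1 and kw == 1:
            b, h, w_, ci = x.shape
            xf = x.reshape(-1, ci)
            df = dout.reshape(-1, self.cout)
            self.w.grad[0, 0] += xf.T @ df
            return (df @ self.w.value[0, 0].T).reshape(x.shape)
        xp = self._pad(x)
        view = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        # dW: correlate input patches with the output gradient
        dw = np.tensordot(view, dout, axes=([0, 1, 2], [0, 1, 2]))
        self.w.grad += dw.transpose(1, 2, 0, 3)  # (cin,kh,kw,cout)->(kh,kw,cin,cout)
        # dX: scatter dout through each kernel tap (9 GEMMs for a 3x3)
        b, h, w_, _ = x.shape
        ph, pw = kh // 2, kw // 2
        dxp = np.zeros((b, h + 2 * ph, w_ + 2 * pw, self.cin), dtype=_DTYPE)
        df = dout.reshape(-1, self.cout)
        for i in range(kh):
            for j in range(kw):
                contrib = (df @ self.w.value[i, j].T).reshape(b, h, w_, self.cin)
                dxp[:, i : i + h, j : j + w_, :] += contrib
        return dxp[:, ph : ph + h, pw : pw + w_, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, H, W)."""

    def __init__(self, channels: int, name: str, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.name = name
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(_DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat.astype(_DTYPE), inv.astype(_DTYPE),
                           x.shape[0] * x.shape[1] * x.shape[2])
        return (self.gamma.value * xhat + self.beta.value).astype(_DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._cache
        axes = (0, 1, 2)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(_DTYPE, copy=False)


class ReLU(Layer):
    activation = "RELU"

    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool1x2(Layer):
    """Max pooling with kernel/stride (1, 2): halves the feature axis only,
    preserving the frame (sequence) axis."""

    name = "Max_pooling"

    def __init__(self, name: str = "Max_pooling"):
        self.name = name
        self._argmax = None
        self._shape = None

    def forward(self, x, training=False):
        b, h, w, c = x.shape
        xr = x.reshape(b, h, w // 2, 2, c)
        if training:
            self._argmax = xr.argmax(axis=3)
            self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        b, h, w, c = self._shape
        dxr = np.zeros((b, h, w // 2, 2, c), dtype=_DTYPE)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], dout[:, :, :, None, :],
                          axis=3)
        return dxr.reshape(b, h, w, c)


class _Add(Layer):
    name = "Add+RELU"
    activation = "RELU"


class ResidualBlock(Layer):
    """conv3x3-BN-ReLU-conv3x3-BN on the main path, 1x1 conv (with bias) on
    the identity path, elementwise Add then ReLU, then (1,2) max pooling."""

    def __init__(self, cin: int, cout: int, names: tuple[str, str, str],
                 rng: np.random.Generator, projection_first: bool = False):
        n1, n2, nproj = names
        self.conv1 = Conv2D(cin, cout, (3, 3), bias=False, name=n1,
                            rng=rng, activation="RELU")
        self.bn1 = BatchNorm(cout, f"{n1}.bn")
        self.relu1 = ReLU(f"{n1}.relu")
        self.conv2 = Conv2D(cout, cout, (3, 3), bias=False, name=n2, rng=rng)
        self.bn2 = BatchNorm(cout, f"{n2}.bn")
        self.proj = Conv2D(cin, cout, (1, 1), bias=True, name=nproj, rng=rng)
        self.add_relu_mask = None
        self.pool = MaxPool1x2()
        self.projection_first = projection_first  # report ordering only
        self.name = f"resblock[{n1}]"

    def params(self):
        ps = []
        for lyr in (self.conv1, self.bn1, self.conv2, self.bn2, self.proj):
            ps.extend(lyr.params())
        return ps

    def forward(self, x, training=False):
        main = self.conv1.forward(x, training)
        main = self.bn1.forward(main, training)
        main = self.relu1.forward(main, training)
        main = self.conv2.forward(main, training)
        main = self.bn2.forward(main, training)
        short = self.proj.forward(x, training)
        summed = main + short
        out = np.maximum(summed, 0)
        if training:
            self.add_relu_mask = summed > 0
        return self.pool.forward(out, training)

    def backward(self, dout):
        d = self.pool.backward(dout)
        d = d * self.add_relu_mask
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        dshort = self.proj.backward(d)
        return dmain + dshort

    def sublayers(self):
        if self.projection_first:
            return [self.proj, self.conv1, self.conv2, _Add(), self.pool]
        return [self.conv1, self.conv2, self.proj, _Add(), self.pool]


class PlainConvBlock(Layer):
    """The shortcut-free counterpart of :class:`ResidualBlock`:
    conv3x3-BN-ReLU-conv3x3-BN-ReLU, then (1,2) max pooling."""

    def __init__(self, cin: int, cout: int, names: tuple[str, str],
                 rng: np.random.Generator):
        n1, n2 = names
        self.conv1 = Conv2D(cin, cout, (3, 3), bias=False, name=n1,
                            rng=rng, activation="RELU")
        self.bn1 = BatchNorm(cout, f"{n1}.bn")
        self.relu1 = ReLU()
        self.conv2 = Conv2D(cout, cout, (3, 3), bias=False, name=n2,
                            rng=rng, activation="RELU")
        self.bn2 = BatchNorm(cout, f"{n2}.bn")
        self.relu2 = ReLU()
        self.pool = MaxPool1x2()
        self.name = f"convblock[{n1}]"

    def params(self):
        ps = []
        for lyr in (self.conv1, self.bn1, self.conv2, self.bn2):
            ps.extend(lyr.params())
        return ps

    def forward(self, x, training=False):
        for lyr in (self.conv1, self.bn1, self.relu1,
                    self.conv2, self.bn2, self.relu2, self.pool):
            x = lyr.forward(x, training)
        return x

    def backward(self, dout):
        for lyr in (self.pool, self.relu2, self.bn2, self.conv2,
                    self.relu1, self.bn1, self.conv1):
            dout = lyr.backward(dout)
        return dout

    def sublayers(self):
        return [self.conv1, self.conv2, self.pool]


# ---------------------------------------------------------------------------
# Sequence layers
# ---------------------------------------------------------------------------

class FrameFlatten(Layer):
    """(B, T, W, C) -> (B, T, W*C): flatten everything but batch and frame."""

    name = "Reshape"

    def __init__(self, name: str = "Reshape"):
        self.name = name
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        b, t = x.shape[:2]
        return np.ascontiguousarray(x).reshape(b, t, -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class FrameDense(Layer):
    """Per-frame (time-distributed) dense layer: (B, T, Din) -> (B, T, Dout)."""

    def __init__(self, din: int, dout: int, name: str,
                 rng: np.random.Generator, activation: str = "-"):
        self.name = name
        self.activation = activation
        self.din, self.dout = din, dout
        w = rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)
        self.w = Param(f"{name}.w", w, l2=True)
        self.b = Param(f"{name}.b", np.zeros(dout))
        self._x = None
        self._mask = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        out = x @ self.w.value + self.b.value
        if self.activation == "RELU":
            if training:
                self._mask = out > 0
            out = np.maximum(out, 0)
        if training:
            self._x = x
        return out

    def backward(self, dout):
        if self.activation == "RELU":
            dout = dout * self._mask
        xf = self._x.reshape(-1, self.din)
        df = np.ascontiguousarray(dout, dtype=_DTYPE).reshape(-1, self.dout)
        self.w.grad += xf.T @ df
        self.b.grad += df.sum(axis=0)
        return (df @ self.w.value.T).reshape(self._x.shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str = "dropout"):
        self.rate = float(rate)
        self.rng = rng
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class _GRUDirection:
    """One direction of a GRU with the dual-bias ("reset-after") gates:

        z = sigmoid(x Wxz + bxz + h Whz + bhz)
        r = sigmoid(x Wxr + bxr + h Whr + bhr)
        n = tanh(x Wxn + bxn + r * (h Whn + bhn))
        h' = z * h + (1 - z) * n

    The reset gate multiplies the recurrent product *after* it is formed,
    and each gate carries separate input and recurrent biases — this is
    the formulation whose parameter count is 3*(din*u + u^2 + 2u).
    """

    def __init__(self, din: int, units: int, name: str, rng: np.random.Generator):
        self.din, self.units = din, units
        s_in = 1.0 / np.sqrt(din)
        s_rec = 1.0 / np.sqrt(units)
        self.wx = Param(f"{name}.wx", rng.uniform(-s_in, s_in, (din, 3 * units)))
        self.wh = Param(f"{name}.wh", rng.uniform(-s_rec, s_rec, (units, 3 * units)))
        self.bx = Param(f"{name}.bx", np.zeros(3 * units))
        self.bh = Param(f"{name}.bh", np.zeros(3 * units))
        self._cache = None

    def params(self):
        return [self.wx, self.wh, self.bx, self.bh]

    def forward(self, x, training=False):
        b, t, _ = x.shape
        u = self.units
        gx = x @ self.wx.value + self.bx.value  # (B,T,3u), one big GEMM
        h = np.zeros((b, u), dtype=_DTYPE)
        hs = np.empty((b, t, u), dtype=_DTYPE)
        if training:
            zs = np.empty((b, t, u), dtype=_DTYPE)
            rs = np.empty((b, t, u), dtype=_DTYPE)
            ns = np.empty((b, t, u), dtype=_DTYPE)
            ghn_s = np.empty((b, t, u), dtype=_DTYPE)
            hprev = np.empty((b, t, u), dtype=_DTYPE)
        for step in range(t):
            gh = h @ self.wh.value + self.bh.value
            z = _sigmoid(gx[:, step, :u] + gh[:, :u])
            r = _sigmoid(gx[:, step, u:2 * u] + gh[:, u:2 * u])
            n = np.tanh(gx[:, step, 2 * u:] + r * gh[:, 2 * u:])
            if training:
                zs[:, step], rs[:, step], ns[:, step] = z, r, n
                ghn_s[:, step] = gh[:, 2 * u:]
                hprev[:, step] = h
            h = z * h + (1 - z) * n
            hs[:, step] = h
        if training:
            self._cache = (x, zs, rs, ns, ghn_s, hprev)
        return hs

    def backward(self, dhs):
        x, zs, rs, ns, ghn_s, hprev = self._cache
        b, t, _ = x.shape
        u = self.units
        dgx = np.zeros((b, t, 3 * u), dtype=_DTYPE)
        dwh = np.zeros_like(self.wh.value)
        dbh = np.zeros(3 * u, dtype=_DTYPE)
        dh = np.zeros((b, u), dtype=_DTYPE)
        whT = self.wh.value.T
        for step in range(t - 1, -1, -1):
            dh = dh + dhs[:, step]
            z, r, n = zs[:, step], rs[:, step], ns[:, step]
            hp, ghn = hprev[:, step], ghn_s[:, step]
            dz = dh * (hp - n)
            dn = dh * (1 - z)
            dh_carry = dh * z
            dn_pre = dn * (1 - n * n)
            dr = dn_pre * ghn
            dghn = dn_pre * r
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            dgh = np.concatenate([dz_pre, dr_pre, dghn], axis=1)
            dgx[:, step, :u] = dz_pre
            dgx[:, step, u:2 * u] = dr_pre
            dgx[:, step, 2 * u:] = dn_pre
            dwh += hp.T @ dgh
            dbh += dgh.sum(axis=0)
            dh = dh_carry + dgh @ whT
        self.wh.grad += dwh
        self.bh.grad += dbh
        xf = x.reshape(-1, self.din)
        dgxf = dgx.reshape(-1, 3 * u)
        self.wx.grad += xf.T @ dgxf
        self.bx.grad += dgxf.sum(axis=0)
        return (dgxf @ self.wx.value.T).reshape(x.shape)


class BiGRU(Layer):
    """Bidirectional sequence-returning GRU; outputs are concatenated, so
    (B, T, Din) -> (B, T, 2*units)."""

    activation = "tanh"

    def __init__(self, din: int, units: int, name: str, rng: np.random.Generator):
        self.name = name
        self.din, self.units = din, units
        self.fwd = _GRUDirection(din, units, f"{name}.fwd", rng)
        self.bwd = _GRUDirection(din, units, f"{name}.bwd", rng)

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, ::-1], training)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        u = self.units
        dxf = self.fwd.backward(np.ascontiguousarray(dout[:, :, :u]))
        dxb = self.bwd.backward(np.ascontiguousarray(dout[:, ::-1, u:]))[:, ::-1]
        return dxf + dxb


class Sigmoid(Layer):
    activation = "sigmoid"

    def __init__(self, name: str = "Output"):
        self.name = name
        self._out = None

    def forward(self, x, training=False):
        out = _sigmoid(x)
        if training:
            self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1 - self._out)


# ---------------------------------------------------------------------------
# Containers and optimization
# ---------------------------------------------------------------------------

class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer], name: str = "model"):
        self.layers = list(layers)
        self.name = name

    def params(self):
        ps = []
        for lyr in self.layers:
            ps.extend(lyr.params())
        return ps

    def forward(self, x, training=False):
        for lyr in self.layers:
            x = lyr.forward(x, training)
        return x

    def backward(self, dout):
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return dout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for lyr in self._all_layers():
            if isinstance(lyr, BatchNorm):
                state[f"{lyr.name}.running_mean"] = lyr.running_mean.copy()
                state[f"{lyr.name}.running_var"] = lyr.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for lyr in self._all_layers():
            if isinstance(lyr, BatchNorm):
                lyr.running_mean[...] = state[f"{lyr.name}.running_mean"]
                lyr.running_var[...] = state[f"{lyr.name}.running_var"]

    def _all_layers(self):
        for lyr in self.layers:
            if isinstance(lyr, (ResidualBlock, PlainConvBlock)):
                for sub in vars(lyr).values():
                    if isinstance(sub, Layer):
                        yield sub
            else:
                yield lyr

    def save(self, path: str | Path, manifest: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        if manifest is not None:
            path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


class Adam:
    """Adaptive-moment optimizer with decoupled-style L2 on flagged params."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 l2_weight: float = 0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.l2_weight = l2_weight
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2_weight and p.l2:
                g = g + 2.0 * self.l2_weight * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
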