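"""Minimal NumPy neural-network layers with hand-derived gradients.

Implements exactly what the implicit autoencoder needs — strided 2-D
convolution and its transpose (via im2col/col2im), dense layers, instance
normalization, leaky ReLU / ReLU / tanh / sigmoid, and Adam — in NCHW
layout. Each layer caches its forward activations and exposes
``backward(dout) -> dx`` which also fills ``layer.grads``. There is no
autograd graph: ``Sequential`` chains layers and the training loop wires
the few cross-network gradient paths by hand.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2d", "Dense", "InstanceNorm2d",
    "LeakyReLU", "ReLU", "Tanh", "Sigmoid", "Flatten", "Sequential", "Adam",
]


# ---------------------------------------------------------------- im2col

def _im2col(x: np.ndarray, k: int, stride: int, pad: int
            ) -> tuple[np.ndarray, tuple[int, int]]:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    return view.reshape(n, c * k * k, ho * wo).copy(), (ho, wo)


def _col2im(cols: np.ndarray, out_shape: tuple[int, int, int, int],
            k: int, stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back to an image."""
    n, c, h, w = out_shape
    img = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            img[:, :, i:i + stride * ho:stride,
                j:j + stride * wo:stride] += cols[:, :, i, j]
    if pad:
        img = img[:, :, pad:-pad, pad:-pad]
    return img


# ----------------------------------------------------------------- layers

class Layer:
    """Base layer: parameter dicts plus cached forward state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


#: default parameter/compute dtype; float64 is used in gradient checks
DTYPE = np.float32


class Conv2d(Layer):
    """Strided convolution, weight (Cout, Cin, k, k), init N(0, 0.02)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype=None) -> None:
        super().__init__()
        dtype = dtype or DTYPE
        self.cin, self.cout, self.k, self.stride, self.pad = (
            cin, cout, k, stride, pad)
        self.params = {
            "W": rng.normal(0.0, 0.02, (cout, cin, k, k)).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }

    def forward(self, x, train=True):
        self._xshape = x.shape
        self._cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._hw = (ho, wo)
        wm = self.params["W"].reshape(self.cout, -1)
        out = np.matmul(wm, self._cols)  # (N, Cout, Ho*Wo)
        out += self.params["b"][None, :, None]
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dout):
        n = dout.shape[0]
        ho, wo = self._hw
        d2 = dout.reshape(n, self.cout, ho * wo)
        wm = self.params["W"].reshape(self.cout, -1)
        self.grads["W"] = np.matmul(
            d2, self._cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.params["W"].shape)
        self.grads["b"] = d2.sum(axis=(0, 2))
        dcols = np.matmul(wm.T, d2)
        return _col2im(dcols, self._xshape, self.k, self.stride, self.pad,
                       ho, wo)


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution, adjoint of Conv2d.

    Output spatial size is ``(H - 1) * stride - 2 * pad + k``.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, dtype=None) -> None:
        super().__init__()
        dtype = dtype or DTYPE
        self.cin, self.cout, self.k, self.stride, self.pad = (
            cin, cout, k, stride, pad)
        self.params = {
            "W": rng.normal(0.0, 0.02, (cin, cout, k, k)).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h - 1) * self.stride - 2 * self.pad + self.k,
                (w - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x, train=True):
        n, cin, h, w = x.shape
        self._x = x
        ho, wo = self._out_hw(h, w)
        wm = self.params["W"].reshape(self.cin, -1)  # (Cin, Cout*k*k)
        cols = np.matmul(wm.T[None], x.reshape(n, cin, h * w))
        out = _col2im(cols, (n, self.cout, ho, wo), self.k, self.stride,
                      self.pad, h, w)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        n, cin, h, w = self._x.shape
        cols, _ = _im2col(dout, self.k, self.stride, self.pad)
        wm = self.params["W"].reshape(self.cin, -1)
        x2 = self._x.reshape(n, cin, h * w)
        self.grads["W"] = np.matmul(
            x2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.params["W"].shape)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return np.matmul(wm[None], cols).reshape(self._x.shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 dtype=None) -> None:
        super().__init__()
        dtype = dtype or DTYPE
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)).astype(dtype),
            "b": np.zeros(nout, dtype=dtype),
        }

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over spatial dims + affine."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=None) -> None:
        super().__init__()
        dtype = dtype or DTYPE
        self.eps = eps
        self.params = {"gamma": np.ones(channels, dtype=dtype),
                       "beta": np.zeros(channels, dtype=dtype)}

    def forward(self, x, train=True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc * self._ivar
        return (self.params["gamma"][None, :, None, None] * self._xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout):
        m = dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        # standard normalization backward, vectorized over (n, c)
        term1 = dxhat
        term2 = dxhat.mean(axis=(2, 3), keepdims=True)
        term3 = self._xhat * (dxhat * self._xhat).mean(axis=(2, 3),
                                                       keepdims=True)
        return self._ivar * (term1 - term2 - term3)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    """A plain layer chain with flat parameter access for the optimizer."""

    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self) -> list[tuple[str, Layer, str]]:
        out = []
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                out.append((f"{i}.{type(layer).__name__}.{key}", layer, key))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: layer.params[key].copy()
                for name, layer, key in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != layer.params[key].shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: expected "
                    f"{layer.params[key].shape}, got {state[name].shape}")
            layer.params[key] = state[name].copy()


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, nets: list[Sequential], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.entries = [e for net in nets for e in net.named_params()]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[key])
                  for name, layer, key in self.entries}
        self.v = {name: np.zeros_like(layer.params[key])
                  for name, layer, key in self.entries}

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for name, layer, key in self.entries:
            g = layer.grads.get(key)
            if g is None:
                continue
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            mhat = self.m[name] / b1c
            vhat = self.v[name] / b2c
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, layer, key in self.entries:
            layer.grads.pop(key, None)
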