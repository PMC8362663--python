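"""Layers with explicit forward/backward passes.

Convolutions use an im2col/col2im lowering; transposed convolution is the
exact adjoint of the strided convolution (zero-insertion upsampling view),
with an explicit output crop so even kernel sizes can hit arbitrary output
shapes.  Array layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np

#: working precision of the framework; float32 keeps the conv lowering fast
DTYPE = np.float32

__all__ = [
    "Layer", "Sequential", "Dense", "Conv2D", "ConvTranspose2D", "BatchNorm",
    "MaxPool2D", "Dropout", "Embedding", "Flatten", "Reshape",
    "ReLU", "LeakyReLU", "Tanh", "Sigmoid",
]


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """Lower (N,C,H,W) into patch columns (N, C, kh, kw, Ho, Wo)."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols


def col2im(
    cols: np.ndarray, out_hw: tuple[int, int], stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch columns back to (N,C,H,W)."""
    n, c, kh, kw, ho, wo = cols.shape
    h, w = out_hw
    x = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class Layer:
    """Base layer: ``params``/``grads`` dicts plus forward/backward."""

    #: names of params that participate in l2 weight decay
    decay_params: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_items(self):
        """Yield (layer, name) for every trainable parameter."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.param_items()
            else:
                for name in layer.params:
                    yield layer, name

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the network function (params + BN statistics)."""
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.state_arrays())
                continue
            out.extend(layer.params.values())
            if isinstance(layer, BatchNorm):
                out.extend([layer.running_mean, layer.running_var])
        return out

    def set_state(self, arrays: list[np.ndarray]) -> None:
        current = self.state_arrays()
        if len(current) != len(arrays):
            raise ValueError("state length mismatch")
        for dst, src in zip(current, arrays):
            dst[...] = src


class Dense(Layer):
    decay_params = ("W",)

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {"W": rng.normal(0.0, scale, (d_in, d_out)).astype(DTYPE),
                       "b": np.zeros(d_out, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv2D(Layer):
    decay_params = ("W",)

    def __init__(
        self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
        stride: int = 1, pad: int = 0,
    ) -> None:
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k = self.kernel
        cols = im2col(x, k, k, self.stride, self.pad)
        n, c, _, _, ho, wo = cols.shape
        self._cols = cols.reshape(n, c * k * k, ho * wo)
        self._in_hw = x.shape[2:]
        w = self.params["W"].reshape(self.c_out, -1)
        out = np.matmul(w, self._cols)
        out += self.params["b"][None, :, None]
        return out.reshape(n, self.c_out, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, ho, wo = dout.shape
        k = self.kernel
        dflat = dout.reshape(n, f, ho * wo)
        self.grads["W"][...] = np.matmul(
            dflat, self._cols.transpose(0, 2, 1)
        ).sum(axis=0).reshape(self.params["W"].shape)
        self.grads["b"][...] = dflat.sum(axis=(0, 2))
        w = self.params["W"].reshape(self.c_out, -1)
        dcols = np.matmul(w.T, dflat)
        dcols = dcols.reshape(n, self.c_in, k, k, ho, wo)
        return col2im(dcols, self._in_hw, self.stride, self.pad)


class ConvTranspose2D(Layer):
    """Transposed (fractionally strided) convolution with output cropping.

    The full output spans ``(H_in − 1)·stride + kernel``; ``crop`` trims
    (top, bottom, left, right).  With kernel 4, stride 2, crop (1,1,1,1) it
    doubles spatial size; with stride 1, crop (1,2,1,2) it preserves it.
    """

    decay_params = ("W",)

    def __init__(
        self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
        stride: int = 1, crop: tuple[int, int, int, int] = (0, 0, 0, 0),
    ) -> None:
        super().__init__()
        self.kernel, self.stride, self.crop = kernel, stride, crop
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, (c_in, c_out, kernel, kernel)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _full_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s = self.kernel, self.stride
        return (h - 1) * s + k, (w - 1) * s + k

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        self._x_flat = x.reshape(n, c, h * w)
        self._in_hw = (h, w)
        wmat = self.params["W"].reshape(self.c_in, -1)
        cols = np.matmul(wmat.T, self._x_flat)
        cols = cols.reshape(n, self.c_out, k, k, h, w)
        full = col2im(cols, self._full_hw(h, w), self.stride, pad=0)
        t, b, l, r = self.crop
        fh, fw = full.shape[2:]
        out = full[:, :, t : fh - b, l : fw - r]
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        k = self.kernel
        t, b, l, r = self.crop
        fh, fw = self._full_hw(*self._in_hw)
        dfull = np.zeros((n, self.c_out, fh, fw), dtype=dout.dtype)
        dfull[:, :, t : fh - b, l : fw - r] = dout
        dcols = im2col(dfull, k, k, self.stride, pad=0)
        dcols = dcols.reshape(n, self.c_out * k * k, self._in_hw[0] * self._in_hw[1])
        wmat = self.params["W"].reshape(self.c_in, -1)
        dx = np.matmul(wmat, dcols)
        self.grads["W"][...] = np.matmul(
            self._x_flat, dcols.transpose(0, 2, 1)
        ).sum(axis=0).reshape(self.params["W"].shape)
        self.grads["b"][...] = dout.sum(axis=(0, 2, 3))
        return dx.reshape(n, self.c_in, *self._in_hw)


class BatchNorm(Layer):
    """Batch normalization over the channel axis (2-D or 4-D inputs)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n_features, dtype=DTYPE),
                       "beta": np.zeros(n_features, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)

    def _axes(self, x: np.ndarray):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x: np.ndarray):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) * self._inv_std.reshape(shp)
        self._m = x.size // x.shape[1]
        return self.params["gamma"].reshape(shp) * self._xhat + self.params["beta"].reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(dout), self._shape(dout)
        self.grads["gamma"][...] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        m = self._m
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shp)
        ) * self._inv_std.reshape(shp)
        return dx


class MaxPool2D(Layer):
    """2×2, stride-2 max pooling; trailing odd rows/columns are dropped."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :, : 2 * ho, : 2 * wo]
        patches = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._argmax = patches.argmax(axis=-1)
        return patches.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, ho, wo = dout.shape
        dpatch = np.zeros((n, c, ho, wo, 4), dtype=dout.dtype)
        np.put_along_axis(dpatch, self._argmax[..., None], dout[..., None], axis=-1)
        dx_c = dpatch.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * ho, 2 * wo)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : 2 * ho, : 2 * wo] = dx_c
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Embedding(Layer):
    def __init__(self, n_items: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": rng.normal(0.0, 0.05, (n_items, dim)).astype(DTYPE)}
        self.grads = {"W": np.zeros((n_items, dim), dtype=DTYPE)}

    def forward(self, idx: np.ndarray, training: bool = True) -> np.ndarray:
        self._idx = np.asarray(idx, dtype=int)
        return self.params["W"][self._idx]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = 0.0
        np.add.at(self.grads["W"], self._idx, dout)
        return np.zeros(self._idx.shape)  # labels carry no gradient


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._in = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)
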