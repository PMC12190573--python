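"""Layers with analytic forward/backward passes, channels-last ``(N,D,H,W,C)``.

All convolutions are stride-1 with odd kernels and "same" zero padding, which
is the only configuration the architecture uses; downsampling is done
exclusively by max-pooling. Convolution lowers to a single BLAS matmul via
im2col, and the backward pass reuses the cached column matrix.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer: stateless unless it owns Parameters or running buffers."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Conv3d(Layer):
    """3D convolution, stride 1, same padding.

    Weight layout is ``(Cin * k^3, Cout)`` so the forward pass is one matmul
    against im2col columns ordered (channel, kz, ky, kx). He-normal init from
    the supplied generator; bias is off by default because every conv in the
    network except the classification head is followed by batch norm.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = False):
        if kernel_size % 2 != 1 or kernel_size < 1:
            raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels))
        self.weight = Parameter(w, name=f"conv{kernel_size}x_{in_channels}to{out_channels}.weight")
        self.bias = Parameter(np.zeros(out_channels), name="conv.bias") if bias else None
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def parameters(self) -> list[Parameter]:
        ps = [self.weight]
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, d, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        p = k // 2
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        else:
            xp = x
        # (N, D, H, W, C, k, k, k) view -> (N*D*H*W, C*k^3) copy
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        cols = win.reshape(n * d * h * w, c * k ** 3)
        out = cols @ self.weight.value
        if self.bias is not None:
            out += self.bias.value
        self._cols = cols if training else None
        self._in_shape = (n, d, h, w, c)
        return out.reshape(n, d, h, w, self.out_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward called without a training-mode forward")
        n, d, h, w, c = self._in_shape
        k, p = self.kernel_size, self.kernel_size // 2
        g2 = grad.reshape(n * d * h * w, self.out_channels)
        self.weight.grad += self._cols.T @ g2
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        dcols = (g2 @ self.weight.value.T).reshape(n, d, h, w, c, k, k, k)
        dxp = np.zeros((n, d + 2 * p, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i:i + d, j:j + h, l:l + w, :] += dcols[:, :, :, :, :, i, j, l]
        self._cols = None
        if p:
            return dxp[:, p:-p, p:-p, p:-p, :]
        return dxp


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels), name="bn.gamma")
        self.beta = Parameter(np.zeros(channels), name="bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (0, 1, 2, 3)
        m = grad.shape[0] * grad.shape[1] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gmean = grad.mean(axis=axes)
        gxmean = (grad * xhat).mean(axis=axes) if m > 1 else np.zeros_like(gmean)
        return self.gamma.value * inv * (grad - gmean - xhat * gxmean)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2. Ties route the gradient to one winner."""

    def __init__(self):
        self._idx = None
        self._in_shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
        xr = (x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
               .transpose(0, 1, 3, 5, 7, 2, 4, 6)
               .reshape(n, d // 2, h // 2, w // 2, c, 8))
        out = xr.max(axis=-1)
        if training:
            self._idx = xr.argmax(axis=-1)
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._in_shape
        dxr = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        self._idx = None
        dx = (dxr.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
                 .transpose(0, 1, 5, 2, 6, 3, 7, 4)
                 .reshape(n, d, h, w, c))
        return dx


class Upsample3d(Layer):
    """Nearest-neighbor 2x upsampling; backward sums gradients per block."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, d, h, w, c = grad.shape
        return (grad.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
                    .sum(axis=(2, 4, 6)))


class Softmax(Layer):
    """Numerically stable softmax over the trailing channel axis."""

    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=-1, keepdims=True)
        if training:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p = self._out
        self._out = None
        return p * (grad - (grad * p).sum(axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for lay in self.layers for p in lay.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad
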