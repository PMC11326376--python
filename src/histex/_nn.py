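"""Minimal neural-network engine: layers, backprop, Adam.

Implements exactly the pieces the spot predictor needs — strided 2-D
convolution (im2col), ReLU, global average pooling, fully connected layers,
residual blocks — each with an explicit backward pass, plus Adam.  Arrays
are float32 by default; every layer honors an explicit ``dtype`` so
gradient checks can run in float64.

Layout conventions: images are ``(N, C, H, W)``; dense activations are
``(N, D)``; linear weights are ``(out, in)``; conv weights are
``(out_ch, in_ch * k * k)`` row-major over ``(in_ch, ki, kj)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ReLU", "Linear", "GlobalAvgPool", "Sequential",
    "ResidualBlock", "FrozenPixelEmbed", "Adam", "he_init",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold ``(N, C, H, W)`` into ``(N, C*k*k, OH*OW)`` patch columns."""
    N, C, H, W = x.shape
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((N, C, k, k, OH, OW), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * OH : stride,
                                  j : j + stride * OW : stride]
    return cols.reshape(N, C * k * k, OH * OW), (OH, OW)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back to image space."""
    N, C, H, W = x_shape
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(N, C, k, k, OH, OW)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * OH : stride,
                j : j + stride * OW : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp


class Layer:
    """Base layer: named parameters, matching gradients, forward/backward."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = (
            in_ch, out_ch, k, stride, pad)
        fan_in = in_ch * k * k
        self.params["W"] = he_init(rng, (out_ch, fan_in), fan_in, dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (OH, OW) = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (cols, x.shape, OH, OW)
        W, b = self.params["W"], self.params["b"]
        out = np.einsum("of,nfp->nop", W, cols, optimize=True)
        return out.reshape(x.shape[0], self.out_ch, OH, OW) + b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, OH, OW = self._cache
        N = x_shape[0]
        d = dout.reshape(N, self.out_ch, OH * OW)
        self.grads["W"] += np.einsum("nop,nfp->of", d, cols, optimize=True)
        self.grads["b"] += d.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.params["W"], d, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) mean over the spatial axes."""

    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (H * W), self._shape
        ).astype(dout.dtype).copy()


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = he_init(rng, (out_dim, in_dim), in_dim, dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class ResidualBlock(Layer):
    """Two 3x3 same-channel convs with an identity skip: relu(x + C2(relu(C1(x))))."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.relu2 = ReLU()
        for name, conv in (("c1", self.conv1), ("c2", self.conv2)):
            for k, v in conv.params.items():
                self.params[f"{name}_{k}"] = v
        self.zero_grad()

    def zero_grad(self) -> None:
        super().zero_grad()
        for name, conv in (("c1", getattr(self, "conv1", None)),
                           ("c2", getattr(self, "conv2", None))):
            if conv is None:
                continue
            for k in conv.params:
                conv.grads[k] = self.grads[f"{name}_{k}"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        return self.relu2.forward(self.conv2.forward(h) + x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dout)
        dh = self.conv2.backward(dy)
        dx_branch = self.conv1.backward(self.relu1.backward(dh))
        return dx_branch + dy


class FrozenPixelEmbed(Layer):
    """Backbone-ablation stand-in: frozen random linear map on downsampled gray pixels.

    Grayscale-averages the patch, average-pools by ``factor``, flattens, and
    applies a fixed (never-trained) random projection to ``out_dim``.
    """

    trainable = False

    def __init__(self, patch_size: int, out_dim: int, factor: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.factor = factor
        side = patch_size // factor
        in_dim = side * side
        self.proj = (rng.standard_normal((out_dim, in_dim)) / np.sqrt(in_dim)).astype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        f = self.factor
        gray = x.mean(axis=1)
        pooled = gray[:, : (H // f) * f, : (W // f) * f]
        pooled = pooled.reshape(N, H // f, f, W // f, f).mean(axis=(2, 4))
        return pooled.reshape(N, -1) @ self.proj.T

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # Frozen and first in the stack: no gradient flows further back.
        return np.zeros(0, dtype=dout.dtype)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def param_items(self) -> list[tuple[str, Layer, str]]:
        """Flat list of (path, owning layer, param name) for trainable params."""
        items = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                for path, owner, name in layer.param_items():
                    items.append((f"{i}.{path}", owner, name))
            elif layer.trainable:
                for name in layer.params:
                    items.append((f"{i}.{name}", layer, name))
        return items


class Adam:
    """Adam with bias correction; state keyed by parameter path."""

    def __init__(self, model: Sequential, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        for path, owner, name in model.param_items():
            self.m[path] = np.zeros_like(owner.params[name])
            self.v[path] = np.zeros_like(owner.params[name])

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for path, owner, name in self.model.param_items():
            g = owner.grads[name]
            m = self.m[path] = self.b1 * self.m[path] + (1 - self.b1) * g
            v = self.v[path] = self.b2 * self.v[path] + (1 - self.b2) * g * g
            owner.params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
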