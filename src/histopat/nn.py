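"""A small, self-contained residual convolutional network in numpy.

Implements exactly what the patch classifier needs — 3x3/1x1/7x7
convolutions (im2col), batch normalization, ReLU, max/global-average
pooling, a linear head, residual blocks with projection shortcuts,
softmax cross-entropy, and SGD with momentum — with hand-written
backward passes.  Weights use He initialization (normal with
std = sqrt(2 / fan_in)), the standard choice for ReLU networks.

Everything is float32, single-threaded numpy, and deterministic given
the initialization RNG, so training runs are reproducible bit-for-bit.
Tensors are laid out NCHW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# im2col plumbing


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> Tuple[np.ndarray, Tuple]:
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sn, sc, sh, sw = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, oh, ow),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
    )
    cols = np.ascontiguousarray(cols.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * oh * ow, c * k * k
    )
    return cols, (n, c, h, w, oh, ow)


def col2im(cols: np.ndarray, shape: Tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, oh, ow = shape
    cols = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : h + pad, pad : w + pad]
    return xp


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: named parameters and their gradients."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, rng) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, k // 2
        fan_in = in_ch * k * k
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch)
        ).astype(np.float32)
        self.out_ch = out_ch

    def forward(self, x, train):
        self._cols, self._shape = im2col(x, self.k, self.stride, self.pad)
        n, _, _, _, oh, ow = self._shape
        out = self._cols @ self.params["W"]
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, _, _, oh, ow = self._shape
        d = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.grads["W"] = self._cols.T @ d
        dcols = d @ self.params["W"].T
        return col2im(dcols, self._shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return (
            self.params["gamma"][None, :, None, None] * self._xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dout):
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * self._istd[None, :, None, None]
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, k // 2

    def forward(self, x, train):
        cols, self._shape = im2col(x, self.k, self.stride, self.pad)
        n, c, h, w, oh, ow = self._shape
        cols = cols.reshape(n * oh * ow, c, self.k * self.k)
        self._argmax = cols.argmax(axis=2)
        out = np.take_along_axis(cols, self._argmax[..., None], axis=2)[..., 0]
        return out.reshape(n, oh, ow, c).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w, oh, ow = self._shape
        d = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, c)
        dcols = np.zeros((n * oh * ow, c, self.k * self.k), dtype=dout.dtype)
        np.put_along_axis(dcols, self._argmax[..., None], d[..., None], axis=2)
        return col2im(
            dcols.reshape(n * oh * ow, c * self.k * self.k),
            self._shape,
            self.k,
            self.stride,
            self.pad,
        )


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / self._hw, self._shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_f, dtype=np.float32)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN plus identity (or 1x1 projection) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng) -> None:
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.proj: Optional[Conv2d] = None
        self.proj_bn: Optional[BatchNorm2d] = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride, rng)
            self.proj_bn = BatchNorm2d(out_ch)
        self.relu_out = ReLU()

    @property
    def sublayers(self) -> List[Layer]:
        subs = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            subs += [self.proj, self.proj_bn]
        return subs

    def forward(self, x, train):
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(out + sc, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        if self.proj is not None:
            dsc = self.proj.backward(self.proj_bn.backward(d))
        else:
            dsc = d
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        return dmain + dsc


# ---------------------------------------------------------------------------
# network


def _walk(layers: Sequence[Layer]) -> List[Layer]:
    flat: List[Layer] = []
    for layer in layers:
        flat.append(layer)
        if isinstance(layer, ResidualBlock):
            flat.extend(layer.sublayers)
    return flat


class Network:
    """A feed-forward stack with a 2D body and a linear head."""

    def __init__(self, body: List[Layer], head: Linear) -> None:
        self.body = body
        self.head = head
        self.pool = GlobalAvgPool()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.body:
            out = layer.forward(out, train)
        out = self.pool.forward(out, train)
        return self.head.forward(out, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.pool.backward(d)
        for layer in reversed(self.body):
            d = layer.backward(d)

    def parameter_layers(self) -> List[Layer]:
        return [l for l in _walk(self.body) + [self.head] if l.params]

    def state_arrays(self) -> Dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and BN running stats."""
        out: Dict[str, np.ndarray] = {}
        for i, layer in enumerate(_walk(self.body) + [self.head]):
            for name, arr in layer.params.items():
                out[f"layer{i:03d}.{name}"] = arr
            if isinstance(layer, BatchNorm2d):
                out[f"layer{i:03d}.running_mean"] = layer.running_mean
                out[f"layer{i:03d}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(_walk(self.body) + [self.head]):
            for name in layer.params:
                layer.params[name] = state[f"layer{i:03d}.{name}"].astype(np.float32)
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"layer{i:03d}.running_mean"].astype(np.float32)
                layer.running_var = state[f"layer{i:03d}.running_var"].astype(np.float32)


def build_network(depth: str, n_classes: int, rng) -> Network:
    """Construct a residual network body by depth descriptor.

    ``"tiny"`` — a 2-stage residual net (8-16-32 channels) sized for CPU
    training on small inputs; ``"18"`` — the standard 18-layer residual
    architecture (slow without a GPU, provided for completeness).
    """
    if depth == "tiny":
        body: List[Layer] = [
            Conv2d(3, 8, 3, 1, rng),
            BatchNorm2d(8),
            ReLU(),
            ResidualBlock(8, 16, 2, rng),
            ResidualBlock(16, 32, 2, rng),
        ]
        return Network(body, Linear(32, n_classes, rng))
    if depth == "18":
        body = [
            Conv2d(3, 64, 7, 2, rng),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, 2),
        ]
        in_ch = 64
        for out_ch, stride in [(64, 1), (64, 1), (128, 2), (128, 1),
                               (256, 2), (256, 1), (512, 2), (512, 1)]:
            body.append(ResidualBlock(in_ch, out_ch, stride, rng))
            in_ch = out_ch
        return Network(body, Linear(512, n_classes, rng))
    raise ValueError(f"unknown depth {depth!r} (use 'tiny' or '18')")


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, net: Network, momentum: float = 0.9) -> None:
        self.layers = net.parameter_layers()
        self.momentum = momentum
        self.velocity = [
            {name: np.zeros_like(arr) for name, arr in layer.params.items()}
            for layer in self.layers
        ]

    def step(self, lr: float) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            for name, arr in layer.params.items():
                v = vel[name]
                v *= self.momentum
                v -= lr * layer.grads[name].astype(np.float32)
                arr += v
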