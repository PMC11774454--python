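"""Minimal seeded convolutional-network core (numpy).

Provides exactly the pieces the package's two learned components need — the
CNN-approximated ideal observer (sigmoid classifier head) and the small
encoder-decoder reconstructor (regression head): stride-1 same-padding 3x3
convolutions, 2x average pooling / nearest-neighbour upsampling, dense
layers, ReLU, Adam, and binary-cross-entropy / mean-squared-error losses.
Everything is float32, channels-last (N, H, W, C), and deterministic given
the seed; the layout keeps the im2col patch matrix contiguous so the heavy
lifting is a single well-shaped GEMM per layer.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["Conv2D", "ReLU", "LeakyReLU", "AvgPool2", "Upsample2",
           "SpaceToDepth", "SkipAdd", "Flatten", "Dense", "Network", "Adam",
           "bce_with_logits", "mse_loss", "sigmoid", "train_network"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: parameters in ``params``, matching grads in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """kxk stride-1 same-padding convolution on (N, H, W, C) input.

    The k*k shifted copies of the padded input are gathered into one
    contiguous patch matrix so forward and backward are each a single GEMM
    (plus cheap slice copies); this is what keeps CPU training fast here.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, *,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = rng.normal(
            0, scale, (k * k * c_in, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, k * k, c), dtype=np.float32)
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            cols[:, :, :, idx, :] = xp[:, di:di + h, dj:dj + w, :]
        return cols.reshape(n * h * w, k * k * c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = self._im2col(x)
        self._cols = cols if train else None
        self._shape = x.shape
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, c = self._shape
        dyr = dy.reshape(n * h * w, self.c_out)
        self.grads["W"] = self._cols.T @ dyr
        self.grads["b"] = dyr.sum(axis=0)
        dcols = (dyr @ self.params["W"].T).reshape(n, h, w, k * k, c)
        self._cols = None
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, idx, :]
        return dxp[:, p:-p, p:-p, :] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LeakyReLU(Layer):
    """Leaky rectifier; the small negative slope prevents dead units in
    very small networks."""

    def __init__(self, alpha: float = 0.1) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class AvgPool2(Layer):
    """2x2 average pooling over (N, H, W, C); assumes even spatial dims."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        up = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2)
        return (up / 4.0).astype(dy.dtype)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling over (N, H, W, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SkipAdd(Layer):
    """Residual container: ``y = x + inner(x)`` (channel counts must match)."""

    def __init__(self, inner: Sequence[Layer]) -> None:
        super().__init__()
        self.inner = list(inner)

    @property
    def sublayers(self) -> list[Layer]:
        return self.inner

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = x
        for layer in self.inner:
            y = layer.forward(y, train=train)
        return x + y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy
        for layer in reversed(self.inner):
            dx = layer.backward(dx)
        return dy + dx


class SpaceToDepth(Layer):
    """Losslessly rearrange (N, H, W, C) -> (N, H/b, W/b, C*b*b).

    Grouping b x b spatial blocks into channels lets every convolution run
    at reduced resolution with a healthy channel count — much faster on CPU
    — without discarding any information.
    """

    def __init__(self, block: int) -> None:
        super().__init__()
        self.block = block

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b = self.block
        n, h, w, c = x.shape
        y = x.reshape(n, h // b, b, w // b, b, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(y).reshape(n, h // b, w // b, c * b * b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = self.block
        n, hb, wb, cbb = dy.shape
        c = cbb // (b * b)
        y = dy.reshape(n, hb, wb, b, b, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(y).reshape(n, hb * b, wb * b, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *,
                 rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = rng.normal(0, scale, (d_out, d_in)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dy.T @ self._x).astype(np.float32)
        self.grads["b"] = dy.sum(axis=0).astype(np.float32)
        dx = dy @ self.params["W"]
        self._x = None
        return dx


class Network:
    """A plain layer stack with forward/backward passes."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Memory-bounded inference pass."""
        outs = [self.forward(x[i:i + batch_size].astype(np.float32),
                             train=False)
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def flat_layers(self) -> list[Layer]:
        """Depth-first expansion of container layers (e.g. SkipAdd)."""
        out: list[Layer] = []

        def walk(layers):
            for layer in layers:
                out.append(layer)
                if hasattr(layer, "sublayers"):
                    walk(layer.sublayers)

        walk(self.layers)
        return out

    def n_params(self) -> int:
        return sum(p.size for layer in self.flat_layers()
                   for p in layer.params.values())

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self.flat_layers()]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.flat_layers(), state):
            for k, v in params.items():
                layer.params[k] = v.copy()


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._layers = net.flat_layers()
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in self._layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in self._layers]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self._layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay and k == "W":
                    g = g + self.weight_decay * p
                m = self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                v = self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    np.float32)


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (loss, dloss/dz)."""
    z = z.reshape(-1)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.astype(np.float32)


def mse_loss(yhat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = yhat - y
    loss = float(np.mean(diff**2))
    return loss, (2.0 * diff / diff.size).astype(np.float32)


def train_network(net: Network, x: np.ndarray, y: np.ndarray, *,
                  loss: str = "bce", epochs: int = 10, batch_size: int = 64,
                  lr: float = 1e-3, weight_decay: float = 0.0, seed: int = 0,
                  x_val: Optional[np.ndarray] = None,
                  y_val: Optional[np.ndarray] = None) -> dict:
    """Adam loop with per-epoch shuffling and step learning-rate decay
    (halved at 1/3 and 2/3 of the run); returns a training history dict."""
    rng = np.random.default_rng(seed)
    opt = Adam(net, lr=lr, weight_decay=weight_decay)
    loss_fn = bce_with_logits if loss == "bce" else mse_loss
    x = x.astype(np.float32)
    history: dict[str, list] = {"loss": [], "val_loss": []}
    for epoch in range(epochs):
        opt.lr = lr * 0.5 ** (3 * epoch // max(epochs, 1))
        order = rng.permutation(x.shape[0])
        epoch_losses = []
        for lo in range(0, x.shape[0], batch_size):
            idx = order[lo:lo + batch_size]
            out = net.forward(x[idx], train=True)
            if loss == "bce":
                lval, dout = loss_fn(out, y[idx])
                dout = dout.reshape(out.shape)
            else:
                lval, dout = loss_fn(out, y[idx])
            net.backward(dout)
            opt.step()
            epoch_losses.append(lval)
        history["loss"].append(float(np.mean(epoch_losses)))
        if x_val is not None:
            out = net.predict(x_val)
            if loss == "bce":
                vl, _ = loss_fn(out, y_val)
            else:
                vl, _ = loss_fn(out, y_val)
            history["val_loss"].append(vl)
    return history
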