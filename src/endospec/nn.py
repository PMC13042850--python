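"""Minimal CPU neural-network layers with hand-written backpropagation.

Just enough machinery for the spectral reconstruction network: 3x3 and 1x1
convolutions (im2col-free, shifted-slice implementation), ReLU, 2x2 average
pooling, nearest-neighbour upsampling, channel concatenation, a squeeze-
excite style channel-attention block with an optional external guidance
embedding, and an Adam optimiser.  Tensors are numpy arrays in NCHW layout.

Each layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. the output and returns the gradient w.r.t. the input while
accumulating parameter gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np

_OFFSETS3 = [(di, dj) for di in range(3) for dj in range(3)]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (cin * 9))
        self.params = {
            "w": rng.normal(0.0, scale, (cout, cin, 3, 3)),
            "b": np.zeros(cout),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        wk = self.params["w"]
        out = np.zeros((n, wk.shape[0], h, w))
        for idx, (di, dj) in enumerate(_OFFSETS3):
            patch = xp[:, :, di : di + h, dj : dj + w]
            out += np.einsum("nchw,oc->nohw", patch, wk[:, :, di, dj], optimize=True)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gp = np.zeros_like(xp)
        wk = self.params["w"]
        for idx, (di, dj) in enumerate(_OFFSETS3):
            patch = xp[:, :, di : di + h, dj : dj + w]
            self.grads["w"][:, :, di, dj] += np.einsum(
                "nohw,nchw->oc", grad, patch, optimize=True
            )
            gp[:, :, di : di + h, dj : dj + w] += np.einsum(
                "nohw,oc->nchw", grad, wk[:, :, di, dj], optimize=True
            )
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        return gp[:, :, 1:-1, 1:-1]


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin)),
            "b": np.zeros(cout),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = np.einsum("nchw,oc->nohw", x, self.params["w"], optimize=True)
        return out + self.params["b"][None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] += np.einsum("nohw,nchw->oc", grad, self._x, optimize=True)
        self.grads["b"] += grad.sum(axis=(0, 2, 3))
        return np.einsum("nohw,oc->nchw", grad, self.params["w"], optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class AvgPool2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class SpectralAttention(Layer):
    """Channel ("spectral") attention with optional encoding guidance.

    Descriptor d = spatial mean of the feature map; a two-layer bottleneck
    MLP maps it to per-channel gates in (0, 1).  When guidance is enabled a
    learned linear embedding of the flattened discrete encoding matrix is
    added to the hidden activation, letting the gates condition on which
    spectral bands the physical encoding actually weighted.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        encoding_vector: np.ndarray | None = None,
        hidden: int | None = None,
    ) -> None:
        super().__init__()
        hidden = hidden or max(channels // 2, 4)
        self.hidden = hidden
        self.enc_vec = None
        self.params = {
            "w1": rng.normal(0.0, np.sqrt(2.0 / channels), (hidden, channels)),
            "b1": np.zeros(hidden),
            "w2": rng.normal(0.0, np.sqrt(2.0 / hidden), (channels, hidden)),
            "b2": np.zeros(channels),
        }
        if encoding_vector is not None:
            v = np.asarray(encoding_vector, float).ravel()
            self.enc_vec = v / max(np.abs(v).max(), 1e-12)
            self.params["wg"] = rng.normal(
                0.0, np.sqrt(1.0 / len(v)), (hidden, len(v))
            )
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        d = x.mean(axis=(2, 3))  # (n, c)
        self._d = d
        pre = d @ self.params["w1"].T + self.params["b1"]
        if self.enc_vec is not None:
            pre = pre + (self.params["wg"] @ self.enc_vec)[None, :]
        self._hmask = pre > 0
        hidden = np.where(self._hmask, pre, 0.0)
        self._hidden = hidden
        att = _sigmoid(hidden @ self.params["w2"].T + self.params["b2"])
        self._att = att
        return x * att[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, att = self._x, self._att
        n, c, h, w = x.shape
        gx = grad * att[:, :, None, None]
        gatt = (grad * x).sum(axis=(2, 3))  # (n, c)
        gz = gatt * att * (1 - att)
        self.grads["w2"] += gz.T @ self._hidden
        self.grads["b2"] += gz.sum(axis=0)
        gh = gz @ self.params["w2"]
        gpre = np.where(self._hmask, gh, 0.0)
        self.grads["w1"] += gpre.T @ self._d
        self.grads["b1"] += gpre.sum(axis=0)
        if self.enc_vec is not None:
            self.grads["wg"] += gpre.sum(axis=0)[:, None] * self.enc_vec[None, :]
        gd = gpre @ self.params["w1"]  # (n, c)
        gx += gd[:, :, None, None] / (h * w)
        return gx


class Adam:
    """Adam optimiser over a list of layers."""

    def __init__(
        self, layers: list, lr: float = 1e-3, beta1: float = 0.9,
        beta2: float = 0.999, eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k in l.params:
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g**2
                l.params[k] -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()
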