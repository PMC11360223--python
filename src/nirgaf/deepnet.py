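"""Compact NumPy CNN with a coordinate-attention variant for 64 x 64 images.

The architecture is the fixed shallow VGG-style stack used throughout this
package (all convolutions 3 x 3, "same" padding, stride 1; pooling 2 x 2,
stride 2):

    Input 64x64x1
    Conv1 3x3x32 ReLU            -> 64 x 64 x 32
    [CoordinateAttention]        -> 64 x 64 x 32   (CACNN only)
    Conv2 3x3x32 ReLU            -> 64 x 64 x 32
    MaxPool 2x2                  -> 32 x 32 x 32
    Conv3 3x3x64 ReLU            -> 32 x 32 x 64
    MaxPool 2x2                  -> 16 x 16 x 64
    Conv4 3x3x128 ReLU           -> 16 x 16 x 128
    MaxPool 2x2                  ->  8 x  8 x 128
    GlobalMaxPool                -> 128
    Dense 128 ReLU (+ dropout)   -> 128
    Dense K softmax              -> K

Forward and backward passes are written by hand on top of BLAS matmuls
(3 x 3 convolutions as nine shifted channel-mixing products), which keeps the
whole stack dependency-free and makes gradient access for Grad-CAM trivial.
Training uses Adam with a stepwise-halving learning-rate schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainConfig",
    "Network",
    "build_network",
    "CNNClassifier",
    "softmax",
    "CoordinateAttention",
]

DTYPE = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: holds parameters in ``params`` and gradients in ``grads``."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())


class Conv3x3(Layer):
    """3 x 3 convolution, stride 1, zero "same" padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name="conv"):
        super().__init__()
        self.name = name
        std = np.sqrt(2.0 / (9 * c_in))
        self.params["W"] = (rng.standard_normal((3, 3, c_in, c_out)) * std).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        b_, h, w, c_in = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp, self._shape = xp, (b_, h, w)
        c_out = self.params["b"].shape[0]
        out = np.broadcast_to(self.params["b"], (b_ * h * w, c_out)).copy()
        W = self.params["W"]
        for di in range(3):
            for dj in range(3):
                patch = xp[:, di : di + h, dj : dj + w, :].reshape(-1, c_in)
                out += patch @ W[di, dj]
        return out.reshape(b_, h, w, c_out)

    def backward(self, dy):
        b_, h, w = self._shape
        c_in = self._xp.shape[-1]
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads["b"] = dyf.sum(axis=0)
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(self._xp)
        for di in range(3):
            for dj in range(3):
                patch = self._xp[:, di : di + h, dj : dj + w, :].reshape(-1, c_in)
                dW[di, dj] = patch.T @ dyf
                dxp[:, di : di + h, dj : dj + w, :] += (dyf @ W[di, dj].T).reshape(
                    b_, h, w, c_in
                )
        self.grads["W"] = dW
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2 x 2 max pooling, stride 2. Ties route to the first maximum."""

    name = "maxpool"

    def forward(self, x, train=False, rng=None):
        b_, h, w, c = x.shape
        xr = x.reshape(b_, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(b_, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b_, h, w, c = self._shape
        dxr = np.zeros((b_, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(b_, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(b_, h, w, c)


class GlobalMaxPool(Layer):
    name = "globalmaxpool"

    def forward(self, x, train=False, rng=None):
        b_, h, w, c = x.shape
        xf = x.reshape(b_, h * w, c)
        self._idx = xf.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(xf, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        b_, h, w, c = self._shape
        dxf = np.zeros((b_, h * w, c), dtype=dy.dtype)
        np.put_along_axis(dxf, self._idx[:, None, :], dy[:, None, :], axis=1)
        return dxf.reshape(b_, h, w, c)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name="dense"):
        super().__init__()
        self.name = name
        std = np.sqrt(2.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * std).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    name = "dropout"

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class CoordinateAttention(Layer):
    """Direction-factorized spatial attention with per-axis gates.

    Each channel is average-pooled along width (giving an H-profile) and
    along height (a W-profile); the two profiles are concatenated, squeezed
    through a shared 1 x 1 transform to ``max(C // reduction, 8)`` channels
    with a ReLU, split back, expanded by two per-direction 1 x 1 transforms
    and passed through sigmoids, yielding gates g_h (per row) and g_w (per
    column). The output is input * g_h * g_w, broadcast over the other axis,
    so the module preserves shape and reduces to the identity when both gates
    are pinned to one (``pin_gates``, a testing/ablation hook).
    """

    name = "coordatt"

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 pin_gates: bool = False):
        super().__init__()
        if reduction <= 0:
            raise ValueError("reduction must be positive")
        self.channels = channels
        self.c_mid = max(channels // reduction, 8)
        self.pin_gates = pin_gates
        std1 = np.sqrt(2.0 / channels)
        std2 = np.sqrt(2.0 / self.c_mid)
        self.params["W1"] = (rng.standard_normal((channels, self.c_mid)) * std1).astype(DTYPE)
        self.params["b1"] = np.zeros(self.c_mid, dtype=DTYPE)
        self.params["Wh"] = (rng.standard_normal((self.c_mid, channels)) * std2).astype(DTYPE)
        self.params["bh"] = np.zeros(channels, dtype=DTYPE)
        self.params["Ww"] = (rng.standard_normal((self.c_mid, channels)) * std2).astype(DTYPE)
        self.params["bw"] = np.zeros(channels, dtype=DTYPE)

    def gates(self, x):
        """Return (g_h, g_w) attention maps of shapes (B,H,C) and (B,W,C)."""
        b_, h, w, c = x.shape
        ph = x.mean(axis=2)  # (B,H,C)
        pw = x.mean(axis=1)  # (B,W,C)
        cat = np.concatenate([ph, pw], axis=1)  # (B,H+W,C)
        z1 = cat @ self.params["W1"] + self.params["b1"]
        a = np.maximum(z1, 0)
        zh = a[:, :h] @ self.params["Wh"] + self.params["bh"]
        zw = a[:, h:] @ self.params["Ww"] + self.params["bw"]
        self._cache = (x, cat, z1, a, h, w)
        return _sigmoid(zh), _sigmoid(zw)

    def forward(self, x, train=False, rng=None):
        gh, gw = self.gates(x)
        if self.pin_gates:
            gh = np.ones_like(gh)
            gw = np.ones_like(gw)
        self._gh, self._gw = gh, gw
        return x * gh[:, :, None, :] * gw[:, None, :, :]

    def backward(self, dy):
        x, cat, z1, a, h, w = self._cache
        gh, gw = self._gh, self._gw
        dx = dy * gh[:, :, None, :] * gw[:, None, :, :]
        if self.pin_gates:
            for k, v in self.params.items():
                self.grads[k] = np.zeros_like(v)
            return dx
        dgh = (dy * x * gw[:, None, :, :]).sum(axis=2)
        dgw = (dy * x * gh[:, :, None, :]).sum(axis=1)
        dzh = dgh * gh * (1 - gh)
        dzw = dgw * gw * (1 - gw)
        ah, aw = a[:, :h], a[:, h:]
        self.grads["Wh"] = ah.reshape(-1, self.c_mid).T @ dzh.reshape(-1, self.channels)
        self.grads["bh"] = dzh.sum(axis=(0, 1))
        self.grads["Ww"] = aw.reshape(-1, self.c_mid).T @ dzw.reshape(-1, self.channels)
        self.grads["bw"] = dzw.sum(axis=(0, 1))
        da = np.concatenate([dzh @ self.params["Wh"].T, dzw @ self.params["Ww"].T], axis=1)
        dz1 = da * (z1 > 0)
        self.grads["W1"] = cat.reshape(-1, self.channels).T @ dz1.reshape(-1, self.c_mid)
        self.grads["b1"] = dz1.sum(axis=(0, 1))
        dcat = dz1 @ self.params["W1"].T
        dx += dcat[:, :h][:, :, None, :] / w
        dx += dcat[:, h:][:, None, :, :] / h
        self._cache = None
        return dx


class Network:
    """An ordered layer stack with manual forward/backward passes."""

    def __init__(self, layers: list[Layer], input_size: int = 64, n_classes: int = 2):
        self.layers = layers
        self.input_size = input_size
        self.n_classes = n_classes

    def forward(self, x, train=False, rng=None, capture: list | None = None):
        """Run the stack; optionally capture every intermediate activation."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} images, got {x.shape[1:3]}"
            )
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
            if capture is not None:
                capture.append((layer.name, x))
        return x

    def backward(self, dlogits, upto: int | None = None):
        """Backpropagate; with ``upto`` return the gradient at that layer's output."""
        dy = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            if upto is not None and i == upto:
                return dy
            dy = self.layers[i].backward(dy)
        return dy

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    def parameters(self):
        for layer in self.layers:
            for key in layer.params:
                yield layer, key

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self.layers)

    def layer_index(self, name: str) -> int:
        for i, layer in enumerate(self.layers):
            if layer.name == name:
                return i
        raise KeyError(name)

    def shape_chain(self, batch: int = 1):
        """Layer-name -> output-shape pairs for one forward pass."""
        cap: list = []
        x = np.zeros((batch, self.input_size, self.input_size, 1), dtype=DTYPE)
        self.forward(x, capture=cap)
        return [(name, tuple(a.shape[1:])) for name, a in cap]


def build_network(
    n_classes: int = 2,
    use_ca: bool = False,
    ca_reduction: int = 8,
    dropout: float = 0.25,
    seed: int = 0,
    pin_ca_gates: bool = False,
    input_size: int = 64,
) -> Network:
    """Assemble the fixed CNN (or CACNN with attention between Conv1 and Conv2)."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [Conv3x3(1, 32, rng, "conv1"), ReLU()]
    if use_ca:
        layers.append(CoordinateAttention(32, ca_reduction, rng, pin_gates=pin_ca_gates))
    layers += [
        Conv3x3(32, 32, rng, "conv2"),
        ReLU(),
        MaxPool2(),
        Conv3x3(32, 64, rng, "conv3"),
        ReLU(),
        MaxPool2(),
        Conv3x3(64, 128, rng, "conv4"),
        ReLU(),
        MaxPool2(),
        GlobalMaxPool(),
        Dense(128, 128, rng, "dense1"),
        ReLU(),
        Dropout(dropout),
        Dense(128, n_classes, rng, "dense2"),
    ]
    return Network(layers, input_size=input_size, n_classes=n_classes)


@dataclass
class TrainConfig:
    """Optimization schedule: Adam with stepwise-halving learning rate.

    ``total_iterations`` counts optimizer steps. With ``batch_size=None`` the
    whole training set is used per step when n <= 512, otherwise mini-batches
    of 32; an explicit batch size overrides both.
    """

    initial_lr: float = 5e-4
    lr_decay: float = 0.5
    decay_every: int = 200
    total_iterations: int = 600
    batch_size: int | None = None
    seed: int = 0

    def lr_at(self, iteration: int) -> float:
        return self.initial_lr * self.lr_decay ** (iteration // self.decay_every)


class _Adam:
    def __init__(self, net: Network, beta1=0.9, beta2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for layer, key in net.parameters():
            self.m[(id(layer), key)] = np.zeros_like(layer.params[key])
            self.v[(id(layer), key)] = np.zeros_like(layer.params[key])

    def step(self, net: Network, lr: float):
        self.t += 1
        for layer, key in net.parameters():
            g = layer.grads[key].astype(DTYPE)
            m = self.m[(id(layer), key)]
            v = self.v[(id(layer), key)]
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[key] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


def train(net: Network, images, labels_onehot, config: TrainConfig):
    """Train with softmax cross-entropy; returns a per-iteration history dict."""
    x = np.asarray(images, dtype=DTYPE)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(labels_onehot, dtype=DTYPE)
    n = len(x)
    if config.batch_size is not None:
        bs = int(config.batch_size)
    else:
        bs = n if n <= 512 else 32
    bs = min(bs, n)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(net)
    history = {"iteration": [], "lr": [], "loss": [], "accuracy": []}
    order = rng.permutation(n)
    cursor = 0
    for it in range(config.total_iterations):
        if bs >= n:
            bidx = np.arange(n)
        else:
            if cursor + bs > n:
                order = rng.permutation(n)
                cursor = 0
            bidx = order[cursor : cursor + bs]
            cursor += bs
        xb, yb = x[bidx], y[bidx]
        logits = net.forward(xb, train=True, rng=rng)
        probs = softmax(logits)
        loss = float(-np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1)))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {it} (lr={config.lr_at(it):.2e}); "
                "inputs may be unnormalized or the learning rate too high"
            )
        acc = float(np.mean(logits.argmax(axis=1) == yb.argmax(axis=1)))
        net.backward((probs - yb) / len(xb))
        opt.step(net, config.lr_at(it))
        history["iteration"].append(it)
        history["lr"].append(config.lr_at(it))
        history["loss"].append(loss)
        history["accuracy"].append(acc)
    return history


@dataclass
class CNNClassifier:
    """fit/predict wrapper giving the network the shallow-model interface.

    Expects pre-encoded (n, 64, 64) grayscale images in [0, 1].
    """

    use_ca: bool = False
    ca_reduction: int = 8
    dropout: float = 0.25
    config: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    net_: Network = field(default=None, repr=False)
    class_order_: np.ndarray = field(default=None, repr=False)
    history_: dict = field(default=None, repr=False)

    def fit(self, images, y) -> "CNNClassifier":
        y = np.asarray(y).astype(str)
        self.class_order_ = np.unique(y)
        if len(self.class_order_) < 2:
            raise ValueError("need at least 2 classes")
        onehot = np.zeros((len(y), len(self.class_order_)), dtype=DTYPE)
        for k, c in enumerate(self.class_order_):
            onehot[y == c, k] = 1.0
        self.net_ = build_network(
            n_classes=len(self.class_order_),
            use_ca=self.use_ca,
            ca_reduction=self.ca_reduction,
            dropout=self.dropout,
            seed=self.seed,
        )
        self.history_ = train(self.net_, images, onehot, self.config)
        return self

    def predict_proba(self, images) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("model is not fitted")
        return self.net_.predict_proba(images)

    def predict(self, images) -> np.ndarray:
        return self.class_order_[self.predict_proba(images).argmax(axis=1)]
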