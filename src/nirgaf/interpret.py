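"""Model interpretation: Grad-CAM heatmaps, ratio of attention (ROA), confidence index.

Grad-CAM weights each feature-map channel of a chosen convolutional layer by
the spatial mean of the target-class logit gradient, sums the weighted maps,
rectifies, bilinearly upsamples to the input resolution and min-max
normalizes to [0, 1]. ROA is the fraction of heatmap pixels above a stated
threshold — a scalar measure of how concentrated the network's attention is.
The confidence index (CI) is the maximum softmax probability for a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .deepnet import CNNClassifier, Network, ReLU, softmax

__all__ = ["AttentionResult", "grad_cam", "roa", "confidence_index", "explain"]


@dataclass(frozen=True)
class AttentionResult:
    """Grad-CAM heatmap with its summary statistics for one sample."""

    heatmap: np.ndarray
    roa: float
    threshold: float
    ci: float
    target_class: str


def _resolve_net(model) -> Network:
    if isinstance(model, Network):
        return model
    if isinstance(model, CNNClassifier):
        if model.net_ is None:
            raise RuntimeError("model is not fitted")
        return model.net_
    raise TypeError(f"unsupported model type {type(model)!r}")


def grad_cam(model, image: np.ndarray, target_class: int | None = None,
             layer: str = "conv4") -> np.ndarray:
    """Class-activation heatmap of one image, normalized to [0, 1].

    ``target_class`` is a class index into the network's output; by default
    the predicted class. ``layer`` names a convolutional layer (its rectified
    activation is used). An all-zero attribution yields an all-zero heatmap
    with a warning rather than an error.
    """
    net = _resolve_net(model)
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, ..., None]
    elif x.ndim == 3:
        x = x[None, ...]
    idx = net.layer_index(layer)
    if idx + 1 < len(net.layers) and isinstance(net.layers[idx + 1], ReLU):
        idx += 1  # use the rectified feature maps
    cap: list = []
    logits = net.forward(x, train=False, capture=cap)
    if target_class is None:
        target_class = int(logits[0].argmax())
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dact = net.backward(dlogits, upto=idx)
    act = cap[idx][1]
    weights = dact[0].mean(axis=(0, 1))  # one weight per channel
    cam = np.maximum((act[0] * weights).sum(axis=-1), 0.0)
    size = net.input_size
    cam = zoom(cam, (size / cam.shape[0], size / cam.shape[1]), order=1)
    peak = cam.max()
    if peak == 0:
        warnings.warn("all-zero Grad-CAM attribution; returning a zero heatmap")
        return np.zeros((size, size))
    return (cam - cam.min()) / (peak - cam.min())


def roa(heatmap: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of heatmap pixels strictly above the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    h = np.asarray(heatmap, dtype=float)
    return float(np.mean(h > threshold))


def confidence_index(model, image: np.ndarray) -> float:
    """Maximum softmax probability of the network for one sample."""
    net = _resolve_net(model)
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, ...]
    probs = softmax(net.forward(x, train=False))
    return float(probs[0].max())


def explain(model: CNNClassifier, image: np.ndarray, threshold: float = 0.5,
            layer: str = "conv4") -> AttentionResult:
    """Full attention summary (heatmap, ROA, CI) for one sample."""
    net = _resolve_net(model)
    probs = softmax(net.forward(np.asarray(image, dtype=np.float32)[None, ...],
                                train=False))[0]
    k = int(probs.argmax())
    heat = grad_cam(model, image, target_class=k, layer=layer)
    label = (
        str(model.class_order_[k]) if isinstance(model, CNNClassifier) else str(k)
    )
    return AttentionResult(heat, roa(heat, threshold), threshold, float(probs[k]), label)
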