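"""Gramian angular field encoding of 1-D spectra into 2-D images.

A spectrum is min-max scaled to [0, 1], optionally downsampled by piecewise
aggregate approximation (PAA), mapped to polar coordinates
(theta_i = arccos(x_i), r_i = i/N), and rendered as an N x N Gramian matrix:

* GASF  M[i, j] = cos(theta_i + theta_j)  (symmetric; diagonal 2*x_i**2 - 1)
* GADF  M[i, j] = sin(theta_i - theta_j)  (antisymmetric; diagonal exactly 0)

Both are computed in the matrix-product form, e.g.
GADF = s' x - x' s with s = sqrt(1 - x**2), which makes the GADF diagonal and
antisymmetry exact in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScaledSpectrum",
    "GAFImage",
    "minmax_scale",
    "paa",
    "to_polar",
    "gasf",
    "gadf",
    "encode_image",
    "flatten_image",
    "save_png",
]


@dataclass(frozen=True)
class ScaledSpectrum:
    """A [0, 1]-scaled series with its polar-coordinate representation."""

    x_tilde: np.ndarray
    theta: np.ndarray
    r: np.ndarray

    @property
    def n(self) -> int:
        return self.x_tilde.shape[0]


@dataclass(frozen=True)
class GAFImage:
    """An N x N Gramian angular field matrix with its generating series."""

    matrix: np.ndarray
    kind: str  # "gasf" | "gadf"
    source: ScaledSpectrum


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale a vector into [0, 1]; order-preserving, min -> 0, max -> 1."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant spectrum cannot be min-max scaled")
    return (x - lo) / (hi - lo)


def paa(values: np.ndarray, target_len: int) -> np.ndarray:
    """Piecewise aggregate approximation: segment means at near-equal widths.

    Segment boundaries sit at round(j*p/m), so segment sizes differ by at most
    one sample. With m == p this is the identity.
    """
    x = np.asarray(values, dtype=float)
    p = x.shape[0]
    m = int(target_len)
    if not 1 <= m <= p:
        raise ValueError(f"target length must satisfy 1 <= m <= p, got m={m}, p={p}")
    if m == p:
        return x.copy()
    bounds = np.round(np.arange(m + 1) * p / m).astype(int)
    return np.array([x[bounds[j] : bounds[j + 1]].mean() for j in range(m)])


def to_polar(x_tilde: np.ndarray) -> ScaledSpectrum:
    """Map a [0, 1] series to polar angles theta = arccos(x) and radii i/N."""
    x = np.asarray(x_tilde, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("scaled values must lie in [0, 1]")
    n = x.shape[0]
    return ScaledSpectrum(x, np.arccos(x), np.arange(1, n + 1) / n)


def _sin_theta(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.clip(1.0 - x * x, 0.0, None))


def gasf(scaled: ScaledSpectrum) -> GAFImage:
    """Gramian angular summation field, cos(theta_i + theta_j)."""
    x = scaled.x_tilde
    s = _sin_theta(x)
    m = np.outer(x, x) - np.outer(s, s)
    return GAFImage(np.clip(m, -1.0, 1.0), "gasf", scaled)


def gadf(scaled: ScaledSpectrum) -> GAFImage:
    """Gramian angular difference field, sin(theta_i - theta_j)."""
    x = scaled.x_tilde
    s = _sin_theta(x)
    m = np.outer(s, x) - np.outer(x, s)
    return GAFImage(np.clip(m, -1.0, 1.0), "gadf", scaled)


def encode_image(
    values: np.ndarray,
    size: int = 64,
    kind: str = "gadf",
    allow_upsample: bool = False,
) -> np.ndarray:
    """Encode a spectrum as a size x size grayscale image in [0, 1].

    Pipeline: min-max scale -> PAA to `size` points -> polar transform ->
    GASF/GADF -> affine map (v + 1) / 2 into [0, 1]. Spectra shorter than
    `size` raise unless ``allow_upsample`` enables linear interpolation.
    """
    if kind not in ("gasf", "gadf"):
        raise ValueError("kind must be 'gasf' or 'gadf'")
    x = minmax_scale(values)
    if x.shape[0] < size:
        if not allow_upsample:
            raise ValueError(
                f"spectrum length {x.shape[0]} < image size {size}; "
                "pass allow_upsample=True to interpolate"
            )
        x = np.interp(np.linspace(0, x.shape[0] - 1, size), np.arange(x.shape[0]), x)
    else:
        x = paa(x, size)
    # PAA averaging can nudge past the scaled extrema only by rounding; angles
    # still need x in [0, 1]
    x = np.clip(x, 0.0, 1.0)
    field = gasf(to_polar(x)) if kind == "gasf" else gadf(to_polar(x))
    return (field.matrix + 1.0) / 2.0


def flatten_image(image: np.ndarray) -> np.ndarray:
    """Row-major flatten; a 64 x 64 image becomes a length-4096 vector."""
    return np.asarray(image).reshape(-1)


def encode_dataset(
    X: np.ndarray, size: int = 64, kind: str = "gadf", allow_upsample: bool = False
) -> np.ndarray:
    """Encode each row of an (n, p) matrix into an (n, size, size) image stack."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack([encode_image(row, size, kind, allow_upsample) for row in X])


def save_png(image: np.ndarray, path) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG (visualization only)."""
    from PIL import Image

    arr = np.round(255.0 * np.clip(image, 0.0, 1.0)).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
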