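"""Spectral preprocessing: SNV, MSC, Savitzky-Golay first derivative, wavelet denoising.

Five named conditions are supported: ``none``, ``sg1st``, ``snv``, ``msc`` and
``cwt`` (wavelet shrinkage with a Daubechies basis). MSC needs a reference
spectrum; ``Preprocessor`` freezes the training-set mean as that reference so
test spectra are corrected against training statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessSpec",
    "Preprocessor",
    "snv",
    "msc",
    "sg_first_derivative",
    "wavelet_denoise",
    "METHODS",
]

METHODS = ("none", "sg1st", "snv", "msc", "cwt")


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering to mean 0, sample SD 1."""
    x = np.asarray(values, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined (zero standard deviation)")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def msc(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (x ~ a + b*ref, OLS) and
    returned as (x - a) / b, undoing additive and multiplicative scatter.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] != x.shape[1]:
        raise ValueError("reference length must match spectrum length")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("constant reference spectrum")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12 * max(1.0, float(np.abs(x).max()))):
        raise ValueError("zero regression slope: MSC undefined for some spectrum")
    a = x.mean(axis=1) - b * ref.mean()
    out = (x - a[:, None]) / b[:, None]
    return out if np.asarray(values).ndim == 2 else out[0]


def sg_first_derivative(values: np.ndarray, window: int = 15, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay first derivative (unit sample spacing)."""
    x = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(x, window, polyorder, deriv=1, axis=-1)


def wavelet_denoise(
    values: np.ndarray, wavelet_name: str = "db8", noise_threshold: float = 0.1
) -> np.ndarray:
    """Multilevel wavelet shrinkage with per-level soft thresholding.

    Detail coefficients at each level are soft-thresholded at
    ``noise_threshold * max(|detail|)`` of that level. Decomposition depth is
    ``floor(log2(p / filter_length))`` capped at 5.
    """
    x = np.asarray(values, dtype=float)
    if not 0 < noise_threshold < 1:
        raise ValueError("noise_threshold must lie in (0, 1)")
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet_name!r}")
    wav = pywt.Wavelet(wavelet_name)
    if x.ndim == 2:
        return np.stack([wavelet_denoise(row, wavelet_name, noise_threshold) for row in x])
    p = x.shape[0]
    if p < wav.dec_len:
        raise ValueError("spectrum shorter than the wavelet filter")
    level = min(5, int(np.floor(np.log2(p / wav.dec_len))))
    level = max(level, 1)
    coeffs = pywt.wavedec(x, wav, level=level)
    out = [coeffs[0]]
    for d in coeffs[1:]:
        peak = np.max(np.abs(d))
        out.append(pywt.threshold(d, noise_threshold * peak, mode="soft") if peak > 0 else d)
    rec = pywt.waverec(out, wav)
    return rec[:p]


@dataclass
class PreprocessSpec:
    """Configuration for one preprocessing condition."""

    method: str = "none"
    window: int = 15
    polyorder: int = 2
    wavelet_name: str = "db8"
    noise_threshold: float = 0.1
    msc_reference: str = "training-mean"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and exceed polyorder")
        if not 0 < self.noise_threshold < 1:
            raise ValueError("noise_threshold must lie in (0, 1)")


class Preprocessor:
    """Fit/transform wrapper around the five preprocessing conditions.

    Only MSC holds state (the reference spectrum, by default the training-set
    mean); the other methods are stateless per-spectrum transforms.
    """

    def __init__(self, spec: PreprocessSpec | None = None):
        self.spec = spec or PreprocessSpec()
        self.reference_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Preprocessor":
        if self.spec.method == "msc":
            self.reference_ = np.asarray(X, dtype=float).mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        m = self.spec.method
        if m == "none":
            return X.copy()
        if m == "snv":
            return snv(X)
        if m == "sg1st":
            return sg_first_derivative(X, self.spec.window, self.spec.polyorder)
        if m == "cwt":
            return wavelet_denoise(X, self.spec.wavelet_name, self.spec.noise_threshold)
        if m == "msc":
            if self.reference_ is None:
                raise RuntimeError("MSC preprocessor must be fitted before transform")
            return msc(X, self.reference_)
        raise AssertionError(m)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
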