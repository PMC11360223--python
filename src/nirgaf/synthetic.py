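"""Synthetic two-class NIR spectra with controllable class signal.

Each spectrum is a sum of Gaussian absorption peaks whose amplitudes differ
between the two classes by a configurable per-peak offset, modulated by a
per-sample multiplicative scatter factor, plus a smooth polynomial baseline
and additive white noise:

    x_i(lambda) = (1 + s_i) * sum_k A_k(class) * exp(-(lambda - c_k)^2 / (2 w_k^2))
                  + baseline(lambda) + eps_i(lambda)

with s_i ~ N(0, scatter_sd^2) and eps ~ N(0, additive_noise_sd^2). This is
the minimal structure under which scatter correction (SNV/MSC) is meaningful
and the Gramian image encoding carries spatially localized class signal. It
does not emulate instrument-specific artifacts (detector nonlinearity,
wavelength drift, correlated noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SpectraSet

__all__ = ["SyntheticConfig", "generate", "benchmark_presets", "class_mean_clean"]


@dataclass
class SyntheticConfig:
    """Parameters of the two-class spectral generator.

    ``peaks`` lists (center nm, width nm, base amplitude) Gaussians; class B
    adds ``class_effect[k]`` to peak k's amplitude. ``baseline`` holds
    polynomial coefficients in the normalized wavelength u in [0, 1]
    (constant first).
    """

    n_per_class: int = 100
    n_points: int = 256
    wavelength_range: tuple[float, float] = (870.0, 1700.0)
    peaks: tuple = ((975.0, 40.0, 0.60), (1160.0, 60.0, 0.80),
                    (1360.0, 50.0, 0.70), (1550.0, 70.0, 0.50))
    class_effect: tuple = (0.12, 0.0, 0.12, 0.0)
    baseline: tuple = (0.20, 0.10)
    scatter_sd: float = 0.05
    additive_noise_sd: float = 0.01
    seed: int = 0
    labels: tuple[str, str] = ("A", "B")
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if len(self.class_effect) != len(self.peaks):
            raise ValueError("class_effect must give one offset per peak")
        if any(w <= 0 for _, w, _ in self.peaks):
            raise ValueError("peak widths must be positive")
        if self.scatter_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_points)


def _peak_sum(config: SyntheticConfig, class_b: bool) -> np.ndarray:
    wl = config.wavelengths
    out = np.zeros_like(wl)
    for (c, w, a), off in zip(config.peaks, config.class_effect):
        amp = a + (off if class_b else 0.0)
        out += amp * np.exp(-((wl - c) ** 2) / (2.0 * w * w))
    return out


def _baseline(config: SyntheticConfig) -> np.ndarray:
    lo, hi = config.wavelength_range
    u = (config.wavelengths - lo) / (hi - lo)
    return sum(coef * u**k for k, coef in enumerate(config.baseline))


def class_mean_clean(config: SyntheticConfig, label: str) -> np.ndarray:
    """Noise-free expected spectrum of one class (scatter averages to 1)."""
    if label not in config.labels:
        raise ValueError(f"unknown label {label!r}")
    return _peak_sum(config, class_b=(label == config.labels[1])) + _baseline(config)


def generate(config: SyntheticConfig) -> SpectraSet:
    """Draw a balanced, seed-reproducible two-class SpectraSet."""
    rng = np.random.default_rng(config.seed)
    base = _baseline(config)
    rows, labels = [], []
    for cls_idx, label in enumerate(config.labels):
        signal = _peak_sum(config, class_b=bool(cls_idx))
        for _ in range(config.n_per_class):
            scatter = rng.normal(0.0, config.scatter_sd)
            noise = rng.normal(0.0, config.additive_noise_sd, size=config.n_points)
            rows.append((1.0 + scatter) * signal + base + noise)
            labels.append(label)
    return SpectraSet(
        np.vstack(rows),
        config.wavelengths,
        np.array(labels, dtype=object),
        positive_label=config.labels[0],
    )


def benchmark_presets() -> dict[str, SyntheticConfig]:
    """Named generator configurations emulating the two benchmark tasks.

    * ``wheat-like``: reflectance-style spectra on an 870-1700 nm axis where
      the two classes differ in two absorption bands (near 975 nm and
      1360 nm), the rest of the profile being shared.
    * ``pear-like``: transmittance-style spectra on a 370-1160 nm axis where
      class B (the "browning" analog) sits below class A across the board,
      most strongly in the 600-800 nm band.
    """
    wheat = SyntheticConfig(name="wheat-like")
    pear = SyntheticConfig(
        n_per_class=100,
        wavelength_range=(370.0, 1160.0),
        peaks=((550.0, 120.0, 0.50), (700.0, 50.0, 0.90), (800.0, 45.0, 0.70)),
        class_effect=(-0.06, -0.18, -0.10),
        baseline=(0.15, 0.05),
        scatter_sd=0.05,
        additive_noise_sd=0.01,
        labels=("healthy", "browning"),
        name="pear-like",
    )
    return {"wheat-like": wheat, "pear-like": pear}


def zero_effect(config: SyntheticConfig) -> SyntheticConfig:
    """The same generator with all class differences removed (null model)."""
    return replace(config, class_effect=tuple(0.0 for _ in config.class_effect),
                   name=config.name + "-null")
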