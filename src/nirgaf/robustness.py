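"""SNR-controlled additive Gaussian noise and robustness curves.

Noise level is stated as a signal-to-noise ratio in decibels,
SNR = 10 log10(Ps / Pn), with signal power Ps the mean squared value of the
clean spectrum. Noise is drawn per sample with per-sample Ps, so every
spectrum is corrupted at the same nominal SNR. Corruption happens on the raw
spectra, *before* any preprocessing, mirroring how noisy acquisitions would
enter a real pipeline.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .evaluate import ModelRecipe, repeated_split_eval
from .io import SpectraSet

__all__ = ["add_noise", "corrupt_dataset", "robustness_curve", "DEFAULT_SNR_GRID"]

DEFAULT_SNR_GRID = (10.0, 20.0, 30.0, math.inf)


def signal_power(values: np.ndarray) -> float:
    """Mean squared value of a spectrum (signal power convention)."""
    x = np.asarray(values, dtype=float)
    return float(np.mean(x * x))


def add_noise(values: np.ndarray, snr_db: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise at the requested SNR (dB).

    Noise variance is Ps * 10**(-snr_db / 10); ``snr_db = inf`` returns the
    input unchanged.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input spectrum must be finite")
    if math.isinf(snr_db):
        return x.copy()
    sigma = math.sqrt(signal_power(x) * 10.0 ** (-snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return x + rng.normal(0.0, sigma, size=x.shape)


def corrupt_dataset(dataset: SpectraSet, snr_db: float, seed: int) -> SpectraSet:
    """Corrupt every spectrum independently at the same nominal SNR."""
    if math.isinf(snr_db):
        return dataset
    rng = np.random.default_rng(seed)
    noisy = np.empty_like(dataset.values)
    for i, row in enumerate(dataset.values):
        sigma = math.sqrt(signal_power(row) * 10.0 ** (-snr_db / 10.0))
        noisy[i] = row + rng.normal(0.0, sigma, size=row.shape)
    return SpectraSet(
        noisy, dataset.wavelengths, dataset.labels, ids=dataset.ids,
        positive_label=dataset.positive_label,
    )


def robustness_curve(
    dataset: SpectraSet,
    recipes: list[ModelRecipe],
    snr_levels=DEFAULT_SNR_GRID,
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Mean accuracy of each recipe at each SNR level.

    For each (recipe, SNR) cell the raw spectra are corrupted, then the full
    repeated-split protocol (split -> preprocess -> encode -> fit -> score)
    runs on the noisy data. Returns one row per cell with mean and SD.
    """
    snr_levels = list(snr_levels)
    if not recipes:
        raise ValueError("need at least one model recipe")
    if len(snr_levels) < 2:
        raise ValueError("need at least two SNR levels")
    rows = []
    for recipe in recipes:
        for snr in snr_levels:
            try:
                noisy = corrupt_dataset(dataset, snr, seed)
                report = repeated_split_eval(noisy, recipe, n_repeats, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"robustness cell failed: recipe={recipe.name} snr_db={snr}"
                ) from exc
            s = report.summary()
            rows.append(
                {
                    "model": recipe.name,
                    "snr_db": snr,
                    "accuracy_mean": s["accuracy_mean"],
                    "accuracy_sd": s["accuracy_sd"],
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
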