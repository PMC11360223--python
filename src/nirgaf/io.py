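"""Spectral dataset container, CSV I/O and reproducible 2:1 train/test splits.

The on-disk format is a plain comma-delimited table: column 1 is a free-text
sample id, column 2 the class label, and the remaining column headers are the
numeric wavelength positions (nm) whose cells hold absorbance/reflectance
values. One row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "SplitIndices", "load_spectra", "save_spectra", "split_2to1"]


@dataclass
class SpectraSet:
    """A matrix of spectra sharing one wavelength axis, with class labels.

    Parameters
    ----------
    values : (n, p) float array
        Absorbance/reflectance, one row per sample.
    wavelengths : (p,) float array
        Strictly increasing wavelength positions in nm.
    labels : (n,) array of str
        Class label per sample.
    ids : (n,) array of str, optional
        Free-text sample identifiers; autogenerated when omitted.
    positive_label : str, optional
        The label treated as "positive" when computing RP/RN. Defaults to the
        first label in sorted order.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None
    positive_label: str | None = None
    classes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n, p) array")
        n, p = self.values.shape
        if self.wavelengths.shape != (p,):
            raise ValueError("wavelengths length must match the number of columns")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectral values must be finite")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match the number of rows")
        if self.ids is None:
            self.ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if self.ids.shape != (n,):
                raise ValueError("ids length must match the number of rows")
        self.classes = np.unique(self.labels.astype(str))
        if self.positive_label is None:
            self.positive_label = str(self.classes[0])
        elif str(self.positive_label) not in set(self.classes):
            raise ValueError(f"positive_label {self.positive_label!r} not among classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            self.values[idx],
            self.wavelengths,
            self.labels[idx],
            ids=self.ids[idx],
            positive_label=self.positive_label
            if self.positive_label in set(self.labels[idx].astype(str))
            else None,
        )


@dataclass(frozen=True)
class SplitIndices:
    """Train/test index partition with the seed that produced it."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr = set(self.train_idx.tolist())
        te = set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(i), "train") for i in self.train_idx] + [
            (int(i), "test") for i in self.test_idx
        ]
        return pd.DataFrame(rows, columns=["index", "role"]).sort_values("index")


def load_spectra(path, positive_label: str | None = None) -> SpectraSet:
    """Read a SpectraSet from a delimited text table.

    The header must be ``id,label,<wl1>,<wl2>,...`` with numeric, strictly
    increasing wavelengths. Ragged or non-numeric rows raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError("expected at least id, label and one wavelength column")
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    try:
        wavelengths = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        bad = np.where(~np.isfinite(values).all(axis=1))[0]
        raise ValueError(f"ragged or non-numeric rows at positions {bad.tolist()}")
    return SpectraSet(
        values,
        wavelengths,
        df.iloc[:, 1].to_numpy(dtype=object),
        ids=df.iloc[:, 0].to_numpy(dtype=object),
        positive_label=positive_label,
    )


def save_spectra(dataset: SpectraSet, path) -> None:
    """Write a SpectraSet in the standard id/label/wavelength CSV layout."""
    df = pd.DataFrame(dataset.values, columns=[repr(float(w)) for w in dataset.wavelengths])
    df.insert(0, "label", dataset.labels)
    df.insert(0, "id", dataset.ids)
    df.to_csv(path, index=False)


def _train_size(n: int) -> int:
    # round(2n/3) with ties upward
    return int(np.floor(2 * n / 3 + 0.5))


def split_2to1(dataset: SpectraSet, seed: int, stratified: bool = True) -> SplitIndices:
    """Partition samples into train/test at a 2:1 ratio.

    Train size is round(2n/3). In stratified mode (default) class proportions
    are preserved within rounding via the largest-remainder method, which
    guarantees every class appears in both parts; each class then needs at
    least 3 members.
    """
    n = dataset.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split 2:1")
    rng = np.random.default_rng(seed)
    n_train = _train_size(n)
    if not stratified:
        perm = rng.permutation(n)
        return SplitIndices(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)

    labels = dataset.labels.astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 3):
        small = classes[counts < 3].tolist()
        raise ValueError(f"stratified split needs >=3 members per class; too few in {small}")
    quota = n_train * counts / n
    base = np.floor(quota).astype(int)
    # largest-remainder: hand out the leftover train slots, then clamp so both
    # parts keep at least one member of every class
    order = np.argsort(-(quota - base))
    for k in order[: n_train - base.sum()]:
        base[k] += 1
    base = np.clip(base, 1, counts - 1)
    while base.sum() > n_train:
        k = int(np.argmax(base - quota))
        base[k] -= 1
    while base.sum() < n_train:
        k = int(np.argmin(base - quota))
        base[k] += 1
    train_parts, test_parts = [], []
    for cls, n_tr in zip(classes, base):
        idx = np.where(labels == cls)[0]
        perm = rng.permutation(len(idx))
        train_parts.append(idx[perm[:n_tr]])
        test_parts.append(idx[perm[n_tr:]])
    return SplitIndices(
        np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts)), seed
    )
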