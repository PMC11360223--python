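"""Evaluation protocol: accuracy/RP/RN metrics, repeated 2:1 splits, sweeps.

Per-run metrics follow the standard misclassification-count form: with P and
N the numbers of positive and negative test samples and Pe, Ne the
misclassified counts of each,

    Accuracy = (1 - (Pe + Ne) / (P + N)) * 100
    RP       = (1 - Pe / P) * 100
    RN       = (1 - Ne / N) * 100

The protocol repeats the stratified 2:1 split / fit / predict cycle (10 times
by default) and reports the mean and sample standard deviation (n-1
denominator) of each metric. A preprocessing sweep runs that protocol for
every (model recipe, preprocessing condition) cell and summarizes each model
by the cross-method SD of its per-method mean accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deepnet import CNNClassifier, TrainConfig
from .gaf import encode_dataset
from .io import SpectraSet, split_2to1
from .preprocess import PreprocessSpec, Preprocessor
from .shallow import PLSDAClassifier, RFGridSearch

__all__ = [
    "RunMetrics",
    "EvalReport",
    "ModelRecipe",
    "metrics",
    "repeated_split_eval",
    "preprocessing_sweep",
    "mean_sd",
]


@dataclass(frozen=True)
class RunMetrics:
    """Counts and percentage metrics for one train/test run."""

    accuracy: float
    rp: float
    rn: float
    P: int
    N: int
    Pe: int
    Ne: int
    seed: int | None = None


def metrics(y_true, y_pred, positive_label) -> RunMetrics:
    """Accuracy, RP and RN (percent) from true/predicted binary labels."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = str(positive_label)
    is_pos = y_true == pos
    P, N = int(is_pos.sum()), int((~is_pos).sum())
    Pe = int(np.sum(is_pos & (y_pred != pos)))
    Ne = int(np.sum(~is_pos & (y_pred == pos)))
    accuracy = (1.0 - (Pe + Ne) / (P + N)) * 100.0
    rp = (1.0 - Pe / P) * 100.0 if P > 0 else float("nan")
    rn = (1.0 - Ne / N) * 100.0 if N > 0 else float("nan")
    return RunMetrics(accuracy, rp, rn, P, N, Pe, Ne)


def mean_sd(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


@dataclass
class EvalReport:
    """Per-run metrics plus mean +/- sample-SD aggregation."""

    per_run: list[RunMetrics]

    @property
    def accuracy_mean(self) -> float:
        return mean_sd([r.accuracy for r in self.per_run])[0]

    @property
    def accuracy_sd(self) -> float:
        return mean_sd([r.accuracy for r in self.per_run])[1]

    def summary(self) -> dict:
        out = {}
        for name in ("accuracy", "rp", "rn"):
            m, s = mean_sd([getattr(r, name) for r in self.per_run])
            out[f"{name}_mean"] = m
            out[f"{name}_sd"] = s
        out["n_runs"] = len(self.per_run)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.per_run])


def _make_model(name: str, seed: int, params: dict):
    if name == "plsda":
        return PLSDAClassifier(**params)
    if name == "rf":
        return RFGridSearch(seed=seed, **params)
    if name in ("cnn", "cacnn"):
        cfg = params.get("config", TrainConfig())
        cfg = replace(cfg, seed=seed)
        extra = {k: v for k, v in params.items() if k != "config"}
        return CNNClassifier(use_ca=(name == "cacnn"), config=cfg, seed=seed, **extra)
    raise ValueError(f"unknown model {name!r}; expected plsda/rf/cnn/cacnn")


@dataclass
class ModelRecipe:
    """A self-contained preprocessing + encoding + model bundle.

    ``encoding`` is "spectra" (model sees preprocessed 1-D spectra), or
    "gadf"/"gasf" (spectra are encoded as images; shallow models receive the
    row-major flattened pixels, networks the 2-D images). All state
    (MSC reference, model weights) is fitted inside each run, so repeated
    evaluations cannot leak between cells.
    """

    model: str = "plsda"
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    encoding: str = "spectra"
    image_size: int = 64
    model_params: dict = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.encoding not in ("spectra", "gadf", "gasf"):
            raise ValueError("encoding must be spectra, gadf or gasf")
        if self.model in ("cnn", "cacnn") and self.encoding == "spectra":
            raise ValueError(f"{self.model} requires an image encoding")
        if self.name is None:
            prefix = "g-" if self.encoding != "spectra" else ""
            self.name = f"{self.preprocess.method}-{prefix}{self.model}"

    def _features(self, X: np.ndarray):
        if self.encoding == "spectra":
            return X
        images = encode_dataset(X, size=self.image_size, kind=self.encoding)
        if self.model in ("cnn", "cacnn"):
            return images
        return images.reshape(len(images), -1)

    def run(self, dataset: SpectraSet, seed: int) -> RunMetrics:
        """One split / preprocess / encode / fit / predict / score cycle."""
        split = split_2to1(dataset, seed=seed, stratified=True)
        Xtr_raw, Xte_raw = dataset.values[split.train_idx], dataset.values[split.test_idx]
        ytr, yte = dataset.labels[split.train_idx], dataset.labels[split.test_idx]
        prep = Preprocessor(self.preprocess).fit(Xtr_raw)
        Xtr, Xte = prep.transform(Xtr_raw), prep.transform(Xte_raw)
        model = _make_model(self.model, seed, self.model_params)
        model.fit(self._features(Xtr), ytr)
        y_pred = model.predict(self._features(Xte))
        m = metrics(yte, y_pred, dataset.positive_label)
        return replace(m, seed=seed)


def repeated_split_eval(
    dataset: SpectraSet,
    recipe: ModelRecipe,
    n_repeats: int = 10,
    base_seed: int = 0,
) -> EvalReport:
    """Run the recipe over seeds base_seed .. base_seed + n_repeats - 1."""
    runs = []
    for k in range(n_repeats):
        seed = base_seed + k
        try:
            runs.append(recipe.run(dataset, seed))
        except Exception as exc:
            raise RuntimeError(f"run with seed {seed} failed for {recipe.name}") from exc
    return EvalReport(runs)


def preprocessing_sweep(
    dataset: SpectraSet,
    recipes: list[ModelRecipe],
    methods: tuple[str, ...] = ("none", "sg1st", "snv", "msc", "cwt"),
    n_repeats: int = 10,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every (model recipe, preprocessing method) cell.

    Returns ``(cells, summary)``: per-cell mean metrics, and per-model mean
    and cross-method sample SD of the per-method mean accuracies.
    """
    if len(methods) < 2:
        raise ValueError("need at least 2 preprocessing methods to sweep")
    rows = []
    for recipe in recipes:
        for method in methods:
            cell = replace(
                recipe, preprocess=replace(recipe.preprocess, method=method), name=None
            )
            report = repeated_split_eval(dataset, cell, n_repeats, base_seed)
            s = report.summary()
            rows.append(
                {
                    "model": recipe.model,
                    "encoding": recipe.encoding,
                    "pretreatment": method,
                    **s,
                }
            )
    cells = pd.DataFrame(rows)
    summary_rows = []
    for (model, enc), grp in cells.groupby(["model", "encoding"], sort=False):
        m, s = mean_sd(grp["accuracy_mean"])
        summary_rows.append(
            {"model": model, "encoding": enc,
             "accuracy_mean_of_means": m, "accuracy_cross_method_sd": s}
        )
    return cells, pd.DataFrame(summary_rows)
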