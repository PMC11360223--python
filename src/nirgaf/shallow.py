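"""Shallow classifiers: PLS-DA with the naive-max decision rule, and a
Gini-criterion random forest with the standard grid search.

PLS-DA regresses a one-hot class indicator matrix on the spectra via NIPALS
PLS2 (components extracted by deflation, maximizing covariance with the
response under orthogonality of the scores), then assigns each sample to the
class whose continuous predicted indicator is largest ("naive max" rule).
Component count is chosen by leave-one-out cross-validation over 1..15.

The random forest delegates its CART/bagging internals to scikit-learn's
Gini-criterion ensemble; the grid is 6 tree counts x 5 depths scored by
stratified 5-fold CV accuracy, ties resolved toward the smaller model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PLSDAClassifier",
    "plsda_select_components",
    "gini_index",
    "RFGridSearch",
    "RF_TREE_GRID",
    "RF_DEPTH_GRID",
]

RF_TREE_GRID = (50, 100, 150, 200, 250, 300)
RF_DEPTH_GRID = (10, 30, 50, 70, 90)


def gini_index(class_frequencies) -> float:
    """Gini impurity of a class-frequency vector: sum_k p_k (1 - p_k)."""
    p = np.asarray(class_frequencies, dtype=float)
    if np.any(p < 0):
        raise ValueError("frequencies must be nonnegative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    return float(np.sum(p * (1.0 - p)))


def _one_hot(y: np.ndarray, class_order: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), len(class_order)))
    for k, c in enumerate(class_order):
        Y[np.asarray(y).astype(str) == c, k] = 1.0
    return Y


def _nipals(X: np.ndarray, Y: np.ndarray, r: int, tol: float = 1e-10, max_iter: int = 500):
    """NIPALS PLS2: returns weight, loading and response-loading matrices.

    X and Y must already be column-centered. Components are extracted one at a
    time; X and Y are deflated by the rank-one score/loading outer products.
    """
    n, p = X.shape
    Xr, Yr = X.copy(), Y.copy()
    W = np.zeros((p, r))
    P = np.zeros((p, r))
    Q = np.zeros((Y.shape[1], r))
    for k in range(r):
        u = Yr[:, np.argmax(Yr.var(axis=0))].copy()
        if np.allclose(u, 0):
            u = Yr[:, 0].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise np.linalg.LinAlgError(
                    f"rank-deficient data: no variance left for component {k + 1}"
                )
            w /= nw
            t = Xr @ w
            tt = t @ t
            if tt == 0:
                raise np.linalg.LinAlgError(
                    f"degenerate score vector at component {k + 1}"
                )
            q = Yr.T @ t / tt
            qq = q @ q
            u = Yr @ q / qq if qq > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        pk = Xr.T @ t / tt
        W[:, k], P[:, k], Q[:, k] = w, pk, q
        Xr -= np.outer(t, pk)
        Yr -= np.outer(t, q)
    return W, P, Q


@dataclass
class PLSDAClassifier:
    """PLS-DA: NIPALS PLS2 regression onto one-hot labels + naive-max rule.

    Parameters
    ----------
    n_components : int or "loocv"
        Fixed latent dimension, or leave-one-out selection over
        ``component_range`` (ties go to the smallest r).
    component_range : iterable of int
        Candidate component counts for LOOCV selection (default 1..15).
    """

    n_components: int | str = "loocv"
    component_range: tuple = tuple(range(1, 16))
    class_order_: np.ndarray = field(default=None, repr=False)
    coef_: np.ndarray = field(default=None, repr=False)
    intercept_: np.ndarray = field(default=None, repr=False)
    W_: np.ndarray = field(default=None, repr=False)
    n_components_: int = field(default=None)

    def fit(self, X: np.ndarray, y) -> "PLSDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(str)
        self.class_order_ = np.unique(y)
        if len(self.class_order_) < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        if self.n_components == "loocv":
            r = plsda_select_components(X, y, self.component_range)
        else:
            r = int(self.n_components)
        r_max = min(len(X) - 1, X.shape[1])
        if not 1 <= r <= r_max:
            raise ValueError(f"n_components must lie in [1, {r_max}], got {r}")
        self.n_components_ = r
        Y = _one_hot(y, self.class_order_)
        x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
        W, P, Q = _nipals(X - x_mean, Y - y_mean, r)
        self.W_ = W
        self.coef_ = W @ np.linalg.solve(P.T @ W, Q.T)
        self.intercept_ = y_mean - x_mean @ self.coef_
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError("feature count does not match the fitted model")
        return X @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # argmax returns the first maximum: ties break to the lowest class index
        return self.class_order_[np.argmax(scores, axis=1)]


def _loocv_scores(X: np.ndarray, Y: np.ndarray, y: np.ndarray, r_values) -> np.ndarray:
    """Per-r LOOCV accuracy, using one max-r NIPALS fit per fold."""
    n = len(X)
    r_values = list(r_values)
    r_max = min(max(r_values), n - 2, X.shape[1])
    correct = np.zeros(len(r_values))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, Yt = X[mask], Y[mask]
        x_mean, y_mean = Xt.mean(axis=0), Yt.mean(axis=0)
        W, P, Q = _nipals(Xt - x_mean, Yt - y_mean, r_max)
        xc = X[i] - x_mean
        for j, r in enumerate(r_values):
            rr = min(r, r_max)
            B = W[:, :rr] @ np.linalg.solve(P[:, :rr].T @ W[:, :rr], Q[:, :rr].T)
            pred = np.argmax(xc @ B + y_mean)
            correct[j] += pred == np.argmax(Y[i])
    return correct / n


def plsda_select_components(X, y, r_range=tuple(range(1, 16))) -> int:
    """Choose the PLS component count maximizing LOOCV accuracy (ties -> smallest)."""
    r_range = tuple(r_range)
    if not r_range:
        raise ValueError("empty component range")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if len(X) > 2000:
        raise ValueError("LOOCV guard: n must be <= 2000")
    Y = _one_hot(y, np.unique(y))
    acc = _loocv_scores(X, Y, y, r_range)
    return int(r_range[int(np.argmax(acc))])


@dataclass
class RFGridSearch:
    """Random forest with the 6 x 5 (trees, depth) grid search.

    Every grid cell is scored by stratified 5-fold CV accuracy; the best cell
    is refitted on the full training data. Ties prefer fewer trees, then a
    shallower depth. Fully deterministic for a fixed seed.
    """

    tree_grid: tuple = RF_TREE_GRID
    depth_grid: tuple = RF_DEPTH_GRID
    seed: int = 0
    model_: RandomForestClassifier = field(default=None, repr=False)
    best_params_: dict = field(default=None)

    def fit(self, X: np.ndarray, y) -> "RFGridSearch":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(str)
        if len(np.unique(y)) < 2:
            raise ValueError("random forest grid search needs at least 2 classes")
        if len(X) < 10:
            raise ValueError("need at least 10 samples")
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=self.seed)
        folds = list(skf.split(X, y))
        best = (-1.0, None)
        for n_trees in self.tree_grid:
            for depth in self.depth_grid:
                acc = 0.0
                for tr, te in folds:
                    clf = RandomForestClassifier(
                        n_estimators=n_trees,
                        max_depth=depth,
                        criterion="gini",
                        random_state=self.seed,
                        n_jobs=1,
                    )
                    clf.fit(X[tr], y[tr])
                    acc += np.mean(clf.predict(X[te]) == y[te])
                acc /= len(folds)
                if acc > best[0]:  # strict: earlier (smaller) cells win ties
                    best = (acc, {"n_trees": n_trees, "max_depth": depth})
        self.best_params_ = best[1]
        self.best_score_ = best[0]
        self.model_ = RandomForestClassifier(
            n_estimators=best[1]["n_trees"],
            max_depth=best[1]["max_depth"],
            criterion="gini",
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("model is not fitted")
        return self.model_.predict(np.asarray(X, dtype=float))
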