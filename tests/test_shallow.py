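import numpy as np
import pytest

from nirgaf.shallow import (
    RF_DEPTH_GRID,
    RF_TREE_GRID,
    PLSDAClassifier,
    RFGridSearch,
    gini_index,
    plsda_select_components,
)


def _gaussian_toy(n_per_class=10, p=8, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, p))
    b = rng.normal(0.0, 1.0, size=(n_per_class, p)) + sep
    X = np.vstack([a, b])
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y


class TestGini:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([0.5, 0.5], 0.5), ([1.0, 0.0], 0.0), ([0.25] * 4, 0.75)],
    )
    def test_values(self, freqs, expected):
        assert gini_index(freqs) == pytest.approx(expected)

    def test_bounds_and_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            gini_index([-0.1, 1.1])
        with pytest.raises(ValueError, match="sum to 1"):
            gini_index([0.3, 0.3])
        assert 0 <= gini_index([0.7, 0.2, 0.1]) <= 1 - 1 / 3


class TestPLSDA:
    def test_exact_linear_relation_reproduced(self):
        # y is a deterministic function of one column: a 1-component fit
        # recovers the one-hot response on the training data
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = np.where(X[:, 2] > 0, "pos", "neg")
        X[:, 2] = np.where(X[:, 2] > 0, 1.0, -1.0)  # make the relation exactly linear
        model = PLSDAClassifier(n_components=1).fit(X[:, [2]], y)
        scores = model.decision_function(X[:, [2]])
        onehot = np.stack([(y == c).astype(float) for c in model.class_order_], axis=1)
        np.testing.assert_allclose(scores, onehot, atol=1e-8)

    def test_invalid_component_counts(self):
        X, y = _gaussian_toy()
        with pytest.raises(ValueError):
            PLSDAClassifier(n_components=0).fit(X, y)
        with pytest.raises(ValueError):
            PLSDAClassifier(n_components=100).fit(X, y)

    def test_separable_toy_perfect_train_and_test(self):
        X, y = _gaussian_toy(n_per_class=10, seed=1)
        Xte, yte = _gaussian_toy(n_per_class=5, seed=2)
        model = PLSDAClassifier(n_components=2).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        assert np.mean(model.predict(Xte) == yte) == 1.0

    def test_matches_reference_pls_regression(self):
        # independent oracle: sklearn's PLSRegression on the same matrices
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 12))
        y = np.where(X[:, 0] + 0.5 * X[:, 3] + 0.1 * rng.normal(size=40) > 0, "A", "B")
        for r in (1, 2, 3):
            ours = PLSDAClassifier(n_components=r).fit(X, y)
            Y = np.stack([(y == c).astype(float) for c in ours.class_order_], axis=1)
            ref = PLSRegression(n_components=r, scale=False).fit(X, Y)
            np.testing.assert_allclose(
                ours.decision_function(X), ref.predict(X), atol=1e-6
            )

    def test_naive_max_tie_breaks_to_first_class(self):
        X, y = _gaussian_toy()
        model = PLSDAClassifier(n_components=1).fit(X, y)
        # force identical score columns
        model.coef_ = np.zeros_like(model.coef_)
        model.intercept_ = np.array([0.5, 0.5])
        assert set(model.predict(X)) == {model.class_order_[0]}

    def test_unfitted_and_mismatch_errors(self):
        X, y = _gaussian_toy()
        with pytest.raises(RuntimeError):
            PLSDAClassifier().predict(X)
        model = PLSDAClassifier(n_components=1).fit(X, y)
        with pytest.raises(ValueError, match="feature count"):
            model.predict(X[:, :3])

    def test_chance_level_on_permuted_labels(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 20))
        accs = []
        for seed in range(10):
            y = np.array(["A", "B"] * 30)
            np.random.default_rng(seed).shuffle(y)
            tr, te = np.arange(40), np.arange(40, 60)
            model = PLSDAClassifier(n_components=3).fit(X[tr], y[tr])
            accs.append(np.mean(model.predict(X[te]) == y[te]))
        mean, sd = np.mean(accs), np.std(accs, ddof=1)
        assert abs(mean - 0.5) < 3 * max(sd, 0.05)


class TestComponentSelection:
    def test_single_informative_direction_selects_one(self):
        # all candidate r give equal LOOCV accuracy -> tie rule picks r=1
        rng = np.random.default_rng(5)
        u = rng.normal(size=(40, 1))
        X = u @ rng.normal(size=(1, 6)) + 1e-6 * rng.normal(size=(40, 6))
        y = np.where(u[:, 0] > 0, "A", "B")
        assert plsda_select_components(X, y, range(1, 6)) == 1

    def test_selected_in_range(self):
        X, y = _gaussian_toy(n_per_class=12, p=20, sep=1.0, seed=9)
        r = plsda_select_components(X, y, range(1, 16))
        assert 1 <= r <= 15

    def test_empty_range_rejected(self):
        X, y = _gaussian_toy()
        with pytest.raises(ValueError, match="empty"):
            plsda_select_components(X, y, ())

    def test_loocv_guard(self):
        X = np.zeros((2001, 3))
        y = np.array(["A", "B"] * 1000 + ["A"])
        with pytest.raises(ValueError, match="2000"):
            plsda_select_components(X, y)


class TestRF:
    def test_default_grid_enumerates_thirty_cells(self):
        assert RF_TREE_GRID == (50, 100, 150, 200, 250, 300)
        assert RF_DEPTH_GRID == (10, 30, 50, 70, 90)
        assert len(RF_TREE_GRID) * len(RF_DEPTH_GRID) == 30

    def test_separable_toy_and_determinism(self):
        X, y = _gaussian_toy(n_per_class=15, seed=4)
        grids = {"tree_grid": (50, 100), "depth_grid": (10, 30)}
        a = RFGridSearch(seed=3, **grids).fit(X, y)
        b = RFGridSearch(seed=3, **grids).fit(X, y)
        assert np.mean(a.predict(X) == y) == 1.0
        assert a.best_params_ == b.best_params_

    def test_tie_break_prefers_smaller_model(self):
        # perfectly separable data: every cell scores 1.0, so the first
        # (fewest trees, shallowest depth) wins
        X, y = _gaussian_toy(n_per_class=15, sep=10.0, seed=6)
        model = RFGridSearch(seed=0, tree_grid=(50, 100), depth_grid=(10, 30)).fit(X, y)
        assert model.best_params_ == {"n_trees": 50, "max_depth": 10}

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((12, 4))
        with pytest.raises(ValueError, match="2 classes"):
            RFGridSearch().fit(X, np.array(["A"] * 12))
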