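import numpy as np
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from depstack import LearnerSpec, default_specs, fit_stacking, grid_search
from depstack.stacking import StackingModel, make_estimator


def _custom(estimator, standardize=False):
    return LearnerSpec("custom", {"estimator": estimator}, standardize=standardize)


def _blobs(rng, n=60, gap=6.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) + gap * y[:, None]
    return X, y


class TestGridSearch:
    def test_singleton_grid_returned_unchanged(self, rng):
        X, y = _blobs(rng)
        spec = grid_search(
            LearnerSpec("knn"), X, y, grid=[{"n_neighbors": 3}], cv_folds=3
        )
        assert spec.params == {"n_neighbors": 3}

    def test_oracle_confirms_winner(self, rng):
        # k=1 memorizes label noise on a noisy toy set; the smoother k should
        # win, and a brute-force re-evaluation on the same folds must agree
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat([0, 1], 40)
        X = y[:, None] + rng.normal(0, 0.9, (80, 1))
        grid = [{"n_neighbors": 1}, {"n_neighbors": 15}]
        spec = grid_search(LearnerSpec("knn"), X, y, grid=grid, cv_folds=5, seed=0)

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        folds = list(skf.split(X, y))
        scores = []
        for params in grid:
            accs = []
            for tr, te in folds:
                est = make_estimator(LearnerSpec("knn", params), seed=0)
                est.fit(X[tr], y[tr])
                accs.append(np.mean(est.predict(X[te]) == y[te]))
            scores.append(np.mean(accs))
        best = grid[int(np.argmax(scores))]
        assert spec.params == best

    def test_tied_scores_take_first_grid_point(self, rng):
        X, y = _blobs(rng, gap=10.0)  # separable: every C scores 1.0
        spec = grid_search(
            LearnerSpec("lr_l2"), X, y,
            grid=[{"C": 1.0}, {"C": 10.0}], cv_folds=3, seed=0,
        )
        assert spec.params == {"C": 1.0}

    def test_empty_grid_rejected(self, rng):
        X, y = _blobs(rng)
        with pytest.raises(ValueError, match="empty"):
            grid_search(LearnerSpec("nb"), X, y, grid=[])


class TestFitStacking:
    def test_constant_learner_gives_constant_meta_column(self, rng):
        X, y = _blobs(rng)
        specs = default_specs()[:2] + [_custom(DummyClassifier(strategy="uniform"))]
        model = fit_stacking(X, y, specs=specs, n_folds=5, seed=0)
        np.testing.assert_allclose(model.oof_[:, 2], 0.5)

    def test_oof_prevents_memorization_leakage(self, rng):
        # overlapping classes: a 1-NN memorizer is perfect on its own
        # training data, but its out-of-fold column cannot be
        y = np.repeat([0, 1], 50)
        X = rng.normal(0, 1.0, (100, 2)) + 0.5 * y[:, None]
        memorizer = _custom(KNeighborsClassifier(n_neighbors=1))
        model = fit_stacking(X, y, specs=[memorizer] + default_specs()[:1],
                             n_folds=5, seed=0)
        oof_acc = np.mean((model.oof_[:, 0] >= 0.5).astype(int) == y)

        resub = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        resub_acc = np.mean(resub.predict(X) == y)
        assert resub_acc == 1.0
        assert oof_acc < 1.0

    def test_fold_bookkeeping_partitions_samples(self, rng):
        X, y = _blobs(rng, n=50)
        model = fit_stacking(X, y, n_folds=5, seed=0)
        counts = np.bincount(model.fold_of_, minlength=5)
        assert counts.sum() == 50 and counts.min() >= 8

    def test_separable_toy_training_accuracy_one(self, rng):
        X, y = _blobs(rng, gap=8.0)
        model = fit_stacking(X, y, n_folds=5, seed=0)
        _, labels = model.predict(X)
        assert np.mean(labels == y) == 1.0

    def test_too_few_samples_rejected(self, rng):
        X, y = _blobs(rng, n=8)
        with pytest.raises(ValueError, match="at least"):
            fit_stacking(X, y, n_folds=5)

    def test_row_permutation_invariance_with_sample_ids(self, rng):
        X, y = _blobs(rng, n=40, gap=2.0)
        ids = [f"u{i:03d}" for i in range(40)]
        model_a = fit_stacking(X, y, n_folds=4, seed=1, sample_ids=ids)

        perm = rng.permutation(40)
        model_b = fit_stacking(
            X[perm], y[perm], n_folds=4, seed=1,
            sample_ids=[ids[i] for i in perm],
        )
        # OOF meta-features agree per sample id, and so do new-data predictions
        np.testing.assert_allclose(model_a.oof_, model_b.oof_[np.argsort(perm)])
        X_new = rng.normal(size=(7, 2))
        np.testing.assert_allclose(
            model_a.predict_proba(X_new), model_b.predict_proba(X_new)
        )


class _StubProba:
    """Minimal fitted-classifier stand-in with a fixed positive probability."""

    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


def _stub_model(fold_ps, meta_identity=True):
    meta = LogisticRegression()
    # fit a steep identity-ish meta model: probability ~ the single column
    z = np.linspace(0.05, 0.95, 40)
    meta.fit(z[:, None], (z >= 0.5).astype(int))
    return StackingModel(
        specs=[LearnerSpec("custom", {"estimator": DummyClassifier()})],
        n_folds=len(fold_ps),
        fold_models=[[_StubProba(p) for p in fold_ps]],
        full_models=None,
        meta_model=meta,
        oof_=np.zeros((1, 1)),
        fold_of_=np.zeros(1, dtype=int),
        n_features_=3,
    )


class TestMetaFeaturesAndPredict:
    def test_fold_average(self):
        model = _stub_model([0.2, 0.4, 0.6, 0.8, 1.0])
        meta = model.meta_features(np.zeros((4, 3)))
        np.testing.assert_allclose(meta, 0.6)

    def test_identical_fold_models_equal_single_model(self):
        model = _stub_model([0.3, 0.3, 0.3])
        np.testing.assert_allclose(model.meta_features(np.zeros((2, 3))), 0.3)

    def test_entries_within_unit_interval(self, rng):
        X, y = _blobs(rng, n=40, gap=1.0)
        model = fit_stacking(X, y, n_folds=4, seed=0)
        meta = model.meta_features(rng.normal(size=(20, 2)))
        assert (meta >= 0).all() and (meta <= 1).all()

    def test_threshold_boundary_is_positive(self):
        model = _stub_model([0.5, 0.5])
        proba, labels = model.predict(np.zeros((1, 3)))
        _, forced = model.predict(np.zeros((1, 3)), threshold=float(proba[0]))
        assert forced[0] == 1  # p >= threshold -> positive

    def test_predict_is_pure(self, rng):
        X, y = _blobs(rng, n=40)
        model = fit_stacking(X, y, n_folds=4, seed=0)
        X_new = rng.normal(size=(10, 2))
        p1, l1 = model.predict(X_new)
        p2, l2 = model.predict(X_new)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(l1, l2)

    def test_feature_count_mismatch_rejected(self, rng):
        X, y = _blobs(rng, n=40)
        model = fit_stacking(X, y, n_folds=4, seed=0)
        with pytest.raises(ValueError, match="features"):
            model.meta_features(np.zeros((3, 5)))

    def test_refit_full_uses_single_model_per_learner(self, rng):
        X, y = _blobs(rng, gap=8.0)
        model = fit_stacking(X, y, n_folds=5, seed=0, refit_full=True)
        assert model.full_models is not None
        _, labels = model.predict(X)
        assert np.mean(labels == y) == 1.0
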