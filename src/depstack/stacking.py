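"""Two-level heterogeneous stacking with out-of-fold meta-features.

Level 1 is a bank of five base learners — RBF-kernel SVM, distance-weighted
k-nearest neighbors, Gaussian naive Bayes, and L1-/L2-penalized logistic
regression.  For each base learner the training set is split into K
stratified folds; the fold-model trained on the other K−1 folds predicts the
positive-class probability of its held-out fold, so every training sample
gets a meta-feature from a model that never saw it (out-of-fold, leakage
free).  Level 2 is a binary logistic regression fitted on the
N × 5 out-of-fold probability matrix against the true labels.

At scoring time each base learner's meta-feature is the mean of its K fold
models' probabilities (optionally a single refit-on-all-training model), and
the meta-learner's probability is thresholded at 0.5 (label 1 on ties).

Fold assignment is keyed to sample ids when given, so permuting training-row
order changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

# meta-features require SVC probability outputs; silence the scikit-learn 1.9
# deprecation chatter until the CalibratedClassifierCV replacement lands
import warnings  # noqa: E402

warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)

KIND_SVM = "svm"
KIND_KNN = "knn"
KIND_NB = "nb"
KIND_LR_L1 = "lr_l1"
KIND_LR_L2 = "lr_l2"
KIND_CUSTOM = "custom"

BASE_KINDS = (KIND_SVM, KIND_KNN, KIND_NB, KIND_LR_L1, KIND_LR_L2)

#: deliberately small default grids, in canonical order (first point wins ties)
DEFAULT_GRIDS: dict[str, list[dict]] = {
    KIND_SVM: [{"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 0.1)],
    KIND_KNN: [{"n_neighbors": k} for k in (3, 5, 7, 9)],
    KIND_NB: [{}],
    KIND_LR_L1: [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    KIND_LR_L2: [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
}


@dataclass(frozen=True)
class LearnerSpec:
    """A base-learner recipe: kind, hyperparameters, preprocessing flag.

    ``kind == "custom"`` takes a prototype estimator under params["estimator"]
    (cloned per fit), which is how tests inject degenerate learners.
    """

    kind: str
    params: dict = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in BASE_KINDS + (KIND_CUSTOM,):
            raise ValueError(f"unknown learner kind {self.kind!r}")


def default_specs() -> list[LearnerSpec]:
    """The five-learner bank in canonical order: SVM, KNN, NB, LG1, LG2."""
    return [LearnerSpec(kind) for kind in BASE_KINDS]


def make_estimator(spec: LearnerSpec, seed: int = 0):
    """Instantiate a (possibly standardizing) sklearn estimator for a spec."""
    if spec.kind == KIND_SVM:
        est = SVC(kernel="rbf", probability=True, random_state=seed, **spec.params)
    elif spec.kind == KIND_KNN:
        est = KNeighborsClassifier(weights="distance", **spec.params)
    elif spec.kind == KIND_NB:
        est = GaussianNB(**spec.params)
    elif spec.kind == KIND_LR_L1:
        est = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=2000,
            random_state=seed, **spec.params,
        )
    elif spec.kind == KIND_LR_L2:
        est = LogisticRegression(
            l1_ratio=0.0, solver="liblinear", max_iter=2000,
            random_state=seed, **spec.params,
        )
    elif spec.kind == KIND_CUSTOM:
        est = clone(spec.params["estimator"])
    else:  # pragma: no cover — guarded in LearnerSpec
        raise ValueError(spec.kind)
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _positive_proba(est, X: np.ndarray, positive_label: int = 1) -> np.ndarray:
    proba = est.predict_proba(X)
    classes = est.classes_ if hasattr(est, "classes_") else est[-1].classes_
    idx = int(np.where(classes == positive_label)[0][0])
    return proba[:, idx]


def grid_search(
    spec: LearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[dict] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> LearnerSpec:
    """Pick the grid point maximizing mean stratified-CV accuracy.

    All points are scored on the same folds (paired); ties go to the first
    point in the grid's canonical order.
    """
    if grid is None:
        grid = DEFAULT_GRIDS.get(spec.kind, [dict(spec.params)])
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    n_splits = min(cv_folds, int(counts.min()))
    if n_splits < 2:
        raise ValueError("a class is too small for stratified CV")
    if n_splits < cv_folds:
        logger.warning(
            "reducing CV folds from %d to %d (smallest class size)",
            cv_folds, n_splits,
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_params, best_score = None, -np.inf
    for params in grid:
        cand = replace(spec, params=dict(params))
        accs = []
        for tr, te in folds:
            est = make_estimator(cand, seed=seed)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[te]) == y[te])))
        score = float(np.mean(accs))
        if score > best_score:  # strict: first tie wins
            best_score, best_params = score, dict(params)
    return replace(spec, params=best_params)


@dataclass
class StackingModel:
    """A fitted two-level stacking classifier.

    ``fold_models[j][k]`` is base learner j's model for fold k; ``oof_``
    holds the out-of-fold meta-feature matrix the meta-learner was fitted
    on; ``fold_of_`` maps each training sample to its held-out fold.
    """

    specs: list[LearnerSpec]
    n_folds: int
    fold_models: list[list]
    full_models: list | None
    meta_model: LogisticRegression
    oof_: np.ndarray
    fold_of_: np.ndarray
    n_features_: int
    threshold: float = 0.5
    positive_label: int = 1

    def meta_features(self, X: np.ndarray) -> np.ndarray:
        """N × n_learners positive-class probability matrix for new samples.

        Per base learner: the mean of its K fold models' probabilities, or
        the refit-on-full-training model when the model was fitted with
        ``refit_full=True``.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got shape {X.shape}"
            )
        cols = []
        for j in range(len(self.specs)):
            if self.full_models is not None:
                cols.append(_positive_proba(self.full_models[j], X, self.positive_label))
            else:
                per_fold = np.stack(
                    [
                        _positive_proba(m, X, self.positive_label)
                        for m in self.fold_models[j]
                    ]
                )
                cols.append(per_fold.mean(axis=0))
        return np.column_stack(cols)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        meta = self.meta_features(X)
        return _positive_proba(self.meta_model, meta, self.positive_label)

    def predict(
        self, X: np.ndarray, threshold: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample positive probability and hard label (1 iff p ≥ threshold)."""
        thr = self.threshold if threshold is None else threshold
        proba = self.predict_proba(X)
        return proba, (proba >= thr).astype(int)


def fit_stacking(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[LearnerSpec] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    sample_ids: Sequence | None = None,
    refit_full: bool = False,
    meta_C: float = 1.0,
    positive_label: int = 1,
) -> StackingModel:
    """Fit the two-level stacking classifier on labeled training data.

    ``sample_ids``, when given, key the fold assignment (and within-fold row
    order) to the ids rather than row positions, so shuffling rows leaves
    the fitted model unchanged.  ``refit_full`` switches test-time
    meta-features from fold-model averaging to a single refit on all
    training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples for {n_folds} folds")
    if specs is None:
        specs = default_specs()
    specs = list(specs)

    if sample_ids is not None:
        order = np.argsort(np.asarray(sample_ids, dtype=object), kind="stable")
    else:
        order = np.arange(n)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=int)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for k, (tr, te) in enumerate(skf.split(X[order], y[order])):
        tr_idx, te_idx = order[np.sort(tr)], order[np.sort(te)]
        folds.append((tr_idx, te_idx))
        fold_of[te_idx] = k

    oof = np.empty((n, len(specs)))
    fold_models: list[list] = []
    full_models: list | None = [] if refit_full else None
    for j, spec in enumerate(specs):
        models_j = []
        for k, (tr_idx, te_idx) in enumerate(folds):
            est = make_estimator(spec, seed=seed + 1009 * j + k)
            try:
                est.fit(X[tr_idx], y[tr_idx])
            except Exception as exc:
                raise RuntimeError(
                    f"base learner {spec.kind!r} failed on fold {k}: {exc}"
                ) from exc
            oof[te_idx, j] = _positive_proba(est, X[te_idx], positive_label)
            models_j.append(est)
        fold_models.append(models_j)
        if refit_full:
            est = make_estimator(spec, seed=seed + 1009 * j + n_folds)
            est.fit(X[order], y[order])
            full_models.append(est)

    meta = LogisticRegression(C=meta_C, solver="lbfgs", max_iter=2000)
    meta.fit(oof[order], y[order])
    return StackingModel(
        specs=specs,
        n_folds=n_folds,
        fold_models=fold_models,
        full_models=full_models,
        meta_model=meta,
        oof_=oof,
        fold_of_=fold_of,
        n_features_=X.shape[1],
        positive_label=positive_label,
    )
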