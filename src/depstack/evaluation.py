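"""Experimental protocol: stratified splits, metrics, CV comparisons, rank tests.

The protocol mirrors a standard classifier-comparison study design:
75/25 stratified train/test split; grid search by 10-fold stratified CV on
the training set; accuracy / precision / recall / F1 on the held-out test
set for three feature-set models (textual only, behavior only, both) × six
methods (five base learners + stacking); a paired 10-fold CV score matrix
per feature-set model feeding a Friedman test across methods and pairwise
Wilcoxon signed-rank tests; and the balanced-vs-unbalanced comparison in
which SMOTE is applied to the training split only and accuracy improvements
are reported in absolute percentage points.

The positive class defaults to depressed (=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .imbalance import SmoteConfig, smote
from .io import GROUP_BEHAVIOR, GROUP_TEXTUAL, FeatureTable
from .stacking import (
    BASE_KINDS,
    LearnerSpec,
    fit_stacking,
    grid_search,
    make_estimator,
)

logger = logging.getLogger(__name__)

METHOD_STACKING = "stacking"
ALL_METHODS = BASE_KINDS + (METHOD_STACKING,)
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")

MODEL_TEXTUAL = "textual"
MODEL_BEHAVIOR = "behavior"
MODEL_BOTH = "both"
MODEL_GROUPS = {
    MODEL_TEXTUAL: (GROUP_TEXTUAL,),
    MODEL_BEHAVIOR: (GROUP_BEHAVIOR,),
    MODEL_BOTH: (GROUP_TEXTUAL, GROUP_BEHAVIOR),
}


@dataclass
class Metrics:
    """Confusion counts and the four derived scores for one prediction set."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: int = 1

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        if denom == 0:
            logger.warning("no positive predictions; precision reported as 0")
            return 0.0
        return self.tp / denom

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            logger.warning("no positive truths; recall reported as 0")
            return 0.0
        return self.tp / denom

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def stratified_split(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index arrays, stratified by class."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int = 1
) -> Metrics:
    """Confusion-matrix metrics for binary predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    pos = positive_class
    return Metrics(
        tp=int(np.sum((y_true == pos) & (y_pred == pos))),
        fp=int(np.sum((y_true != pos) & (y_pred == pos))),
        tn=int(np.sum((y_true != pos) & (y_pred != pos))),
        fn=int(np.sum((y_true == pos) & (y_pred != pos))),
        positive_class=pos,
    )


def f1_from_pr(p: float, r: float, digits: int | None = None) -> float:
    """Harmonic mean 2pr/(p+r); ``digits`` applies half-even report rounding."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p + r == 0:
        raise ValueError("f1 undefined for p = r = 0")
    f1 = 2 * p * r / (p + r)
    if digits is not None:
        f1 = float(np.round(f1, digits))  # numpy rounds half to even
    return f1


def improvement_pp(after: float, before: float) -> float:
    """Absolute percentage-point change 100·(after − before), 2 decimals."""
    if not (0 <= after <= 1 and 0 <= before <= 1):
        raise ValueError("accuracies must lie in [0, 1]")
    return float(np.round(100.0 * (after - before), 2))


def friedman_test(scores: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Friedman rank test across methods (columns) over paired units (rows).

    Returns (chi-square statistic with tie-corrected mid-ranks, dof, p).
    Identical columns give statistic 0 (p reported as 1).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 methods and >= 2 units")
    if np.ptp(arr, axis=1).max() == 0:
        return 0.0, arr.shape[1] - 1, 1.0
    if arr.shape[1] >= 3:
        stat, p = stats.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
        return float(stat), arr.shape[1] - 1, float(p)
    # scipy requires >= 3 methods; same statistic computed directly for k = 2
    n, k = arr.shape
    ranks = np.vstack([stats.rankdata(row) for row in arr])
    ties = sum(
        float(np.sum(np.fromiter(
            ((np.sum(row == v)) ** 3 - np.sum(row == v) for v in np.unique(row)),
            dtype=float,
        )))
        for row in arr
    )
    correction = 1.0 - ties / (n * k * (k * k - 1))
    stat = (
        12.0 / (n * k * (k + 1)) * float(np.sum(ranks.sum(axis=0) ** 2))
        - 3.0 * n * (k + 1)
    ) / correction
    return float(stat), k - 1, float(stats.chi2.sf(stat, k - 1))


def wilcoxon_pairwise(scores: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank p-values for every method pair.

    Zero differences are dropped; the exact null distribution is used for
    ≤ 25 nonzero differences without rank ties, the tie-corrected normal
    approximation otherwise.  All-zero differences give p = 1 with a
    warning.  The matrix is symmetric with unit diagonal.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(np.asarray(scores, dtype=float))
    methods = list(scores.columns)
    out = pd.DataFrame(np.ones((len(methods), len(methods))),
                       index=methods, columns=methods)
    for a in range(len(methods)):
        for b in range(a + 1, len(methods)):
            d = scores.iloc[:, a].to_numpy() - scores.iloc[:, b].to_numpy()
            if np.all(d == 0):
                logger.warning(
                    "all differences zero for %s vs %s; p = 1",
                    methods[a], methods[b],
                )
                p = 1.0
            else:
                res = stats.wilcoxon(
                    d, zero_method="wilcox", alternative="two-sided", method="auto"
                )
                p = float(res.pvalue)
            out.iloc[a, b] = out.iloc[b, a] = p
    return out


@dataclass
class ExperimentConfig:
    """Knobs of the comparison protocol; defaults follow the study design."""

    test_fraction: float = 0.25
    cv_folds: int = 10
    grid_cv_folds: int | None = None  # None → cv_folds
    stacking_folds: int = 5
    seed: int = 0
    positive_class: int = 1
    models: tuple[str, ...] = (MODEL_TEXTUAL, MODEL_BEHAVIOR, MODEL_BOTH)
    methods: tuple[str, ...] = ALL_METHODS
    grids: dict[str, list[dict]] | None = None  # None → stacking.DEFAULT_GRIDS
    balance_models: tuple[str, ...] = (MODEL_BOTH,)
    smote_k: int = 5
    run_rank_tests: bool = True


@dataclass
class MetricsReport:
    """All tables the protocol produces.

    ``test_metrics``: MultiIndex (model, method) × the four metrics.
    ``cv_scores``: per feature-set model, a folds × methods accuracy matrix
    (paired folds).  ``friedman``: per model, (stat, dof, p).  ``wilcoxon``:
    per model, the symmetric p-value matrix.  ``balance``: per method,
    unbalanced/balanced test accuracy and the improvement in percentage
    points.
    """

    test_metrics: pd.DataFrame
    cv_scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    friedman: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    wilcoxon: dict[str, pd.DataFrame] = field(default_factory=dict)
    balance: pd.DataFrame | None = None
    tuned_specs: dict[str, dict[str, LearnerSpec]] = field(default_factory=dict)


def _fit_predict(
    method: str,
    tuned: dict[str, LearnerSpec],
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    cfg: ExperimentConfig,
    seed: int,
) -> np.ndarray:
    if method == METHOD_STACKING:
        model = fit_stacking(
            X_tr, y_tr,
            specs=[tuned[k] for k in BASE_KINDS if k in tuned],
            n_folds=cfg.stacking_folds,
            seed=seed,
            positive_label=cfg.positive_class,
        )
        _, pred = model.predict(X_te)
        if cfg.positive_class != 1:
            pred = np.where(pred == 1, cfg.positive_class, 1 - cfg.positive_class)
        return pred
    est = make_estimator(tuned[method], seed=seed)
    est.fit(X_tr, y_tr)
    return est.predict(X_te)


def run_experiment(table: FeatureTable, cfg: ExperimentConfig | None = None) -> MetricsReport:
    """Run the full comparison protocol on a labeled feature table."""
    cfg = cfg or ExperimentConfig()
    if table.labels is None:
        raise ValueError("run_experiment requires a labeled table")
    grid_cv = cfg.grid_cv_folds or cfg.cv_folds

    rows = []
    cv_scores: dict[str, pd.DataFrame] = {}
    friedman: dict[str, tuple[float, int, float]] = {}
    wilcoxon: dict[str, pd.DataFrame] = {}
    tuned_by_model: dict[str, dict[str, LearnerSpec]] = {}
    balance_rows = []

    for model_name in cfg.models:
        sub = table.subset_groups(MODEL_GROUPS[model_name])
        X, y = sub.X, table.labels
        tr, te = stratified_split(X, y, cfg.test_fraction, seed=cfg.seed)
        X_tr, y_tr, X_te, y_te = X[tr], y[tr], X[te], y[te]

        logger.info("model %s: tuning %d base learners", model_name, len(BASE_KINDS))
        tuned: dict[str, LearnerSpec] = {}
        for kind in BASE_KINDS:
            grid = None if cfg.grids is None else cfg.grids.get(kind)
            tuned[kind] = grid_search(
                LearnerSpec(kind), X_tr, y_tr,
                grid=grid, cv_folds=grid_cv, seed=cfg.seed,
            )
        tuned_by_model[model_name] = tuned

        for method in cfg.methods:
            pred = _fit_predict(method, tuned, X_tr, y_tr, X_te, cfg, cfg.seed)
            m = compute_metrics(y_te, pred, cfg.positive_class)
            rows.append({"model": model_name, "method": method, **m.as_dict()})

        if cfg.run_rank_tests:
            skf = StratifiedKFold(
                n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed
            )
            folds = list(skf.split(X_tr, y_tr))  # same folds for every method
            mat = np.empty((len(folds), len(cfg.methods)))
            for j, method in enumerate(cfg.methods):
                for i, (ftr, fte) in enumerate(folds):
                    pred = _fit_predict(
                        method, tuned, X_tr[ftr], y_tr[ftr], X_tr[fte],
                        cfg, cfg.seed + i,
                    )
                    mat[i, j] = float(np.mean(pred == y_tr[fte]))
            cv_df = pd.DataFrame(mat, columns=list(cfg.methods))
            cv_scores[model_name] = cv_df
            friedman[model_name] = friedman_test(cv_df)
            wilcoxon[model_name] = wilcoxon_pairwise(cv_df)

        if model_name in cfg.balance_models:
            smote_cfg = SmoteConfig(k_neighbors=cfg.smote_k, seed=cfg.seed)
            X_bal, y_bal = smote(X_tr, y_tr, smote_cfg)
            for method in cfg.methods:
                pred_u = _fit_predict(method, tuned, X_tr, y_tr, X_te, cfg, cfg.seed)
                pred_b = _fit_predict(method, tuned, X_bal, y_bal, X_te, cfg, cfg.seed)
                acc_u = compute_metrics(y_te, pred_u, cfg.positive_class).accuracy
                acc_b = compute_metrics(y_te, pred_b, cfg.positive_class).accuracy
                balance_rows.append(
                    {
                        "model": model_name,
                        "method": method,
                        "accuracy_unbalanced": acc_u,
                        "accuracy_balanced": acc_b,
                        "improve_pp": improvement_pp(acc_b, acc_u),
                    }
                )

    test_metrics = pd.DataFrame(rows).set_index(["model", "method"])
    balance = pd.DataFrame(balance_rows) if balance_rows else None
    return MetricsReport(
        test_metrics=test_metrics,
        cv_scores=cv_scores,
        friedman=friedman,
        wilcoxon=wilcoxon,
        balance=balance,
        tuned_specs=tuned_by_model,
    )
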