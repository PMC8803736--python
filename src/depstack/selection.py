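"""Hybrid feature selection: wrapper + embedded + filter weight fusion.

Three importance scorers each produce a weight vector normalized to sum 1:

* ``rfe_weights`` — recursive feature elimination with a random-forest
  scorer (wrapper).  Features are eliminated one per step down to a single
  survivor; the elimination order is mapped linearly to weights
  w_i ∝ n − rank_i + 1 (rank 1 = last survivor).
* ``tree_weights`` — mean impurity-decrease importances of an
  extremely-randomized-trees ensemble (embedded).
* ``mi_weights`` — per-feature mutual information with the label
  (nearest-neighbor estimator, k=3, clamped at 0), normalized by its sum
  (filter).

The fusion strategy is the element-wise sum W = Wr + We + Wm; the bottom
``drop_fraction`` of features by fused weight (floor rounding, ties dropping
the later-declared feature) are removed.  All scorers see z-scored copies of
the data so the three weight vectors are commensurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, mutual_info_classif
from sklearn.preprocessing import StandardScaler

from .io import FeatureTable

logger = logging.getLogger(__name__)

SOURCE_RFE = "rfe"
SOURCE_TREES = "extra_trees"
SOURCE_MI = "mutual_info"


@dataclass
class WeightVector:
    """Per-feature importance from one scorer, normalized to sum 1."""

    feature_names: list[str]
    weights: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_names),):
            raise ValueError("weights length != feature_names length")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")


@dataclass
class FusedWeights:
    """Element-wise sum W = Wr + We + Wm with the component breakdown kept."""

    feature_names: list[str]
    fused: np.ndarray
    components: dict[str, np.ndarray]


@dataclass
class SelectionResult:
    """Outcome of dropping the bottom fraction of features by fused weight."""

    retained: list[str]  # in original schema order
    dropped: list[str]
    drop_fraction: float
    fused: FusedWeights

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    return X, y


def _standardize(X: np.ndarray) -> np.ndarray:
    return StandardScaler().fit_transform(X)


def rfe_weights(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_estimators: int = 100,
) -> WeightVector:
    """Wrapper importances via recursive feature elimination (random forest)."""
    X, y = _validate_xy(X, y)
    rfe = RFE(
        RandomForestClassifier(n_estimators=n_estimators, random_state=seed),
        n_features_to_select=1,
        step=1,
    )
    rfe.fit(_standardize(X), y)
    n = X.shape[1]
    raw = (n - rfe.ranking_ + 1).astype(float)  # rank 1 = last survivor
    return WeightVector(feature_names, raw / raw.sum(), SOURCE_RFE)


def tree_weights(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_estimators: int = 200,
) -> WeightVector:
    """Embedded importances: impurity decrease of extremely randomized trees."""
    X, y = _validate_xy(X, y)
    forest = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(_standardize(X), y)
    raw = forest.feature_importances_.astype(float)
    if raw.sum() <= 0:
        logger.warning("all tree importances zero; using uniform weights")
        raw = np.ones_like(raw)
    return WeightVector(feature_names, raw / raw.sum(), SOURCE_TREES)


def mi_weights(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_neighbors: int = 3,
) -> WeightVector:
    """Filter importances: each feature's share of total mutual information."""
    X, y = _validate_xy(X, y)
    mi = mutual_info_classif(
        _standardize(X), y, n_neighbors=n_neighbors, random_state=seed
    )
    raw = np.clip(mi, 0.0, None)
    if raw.sum() <= 0:
        logger.warning("all mutual-information estimates zero; uniform weights")
        raw = np.ones_like(raw)
    return WeightVector(feature_names, raw / raw.sum(), SOURCE_MI)


def fuse_weights(
    wr: WeightVector, we: WeightVector, wm: WeightVector
) -> FusedWeights:
    """W = Wr + We + Wm, refusing silently realigned feature lists."""
    for other in (we, wm):
        if other.feature_names != wr.feature_names:
            raise ValueError("weight vectors disagree on feature names/order")
    fused = wr.weights + we.weights + wm.weights
    return FusedWeights(
        feature_names=list(wr.feature_names),
        fused=fused,
        components={wr.source: wr.weights, we.source: we.weights, wm.source: wm.weights},
    )


def select_features(
    fused: FusedWeights, drop_fraction: float = 0.20
) -> SelectionResult:
    """Drop the floor(drop_fraction·n) features with smallest fused weight.

    Ties are broken by dropping the feature declared later in the schema, so
    earlier-declared features survive.  Retained features keep schema order.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    n = len(fused.feature_names)
    n_drop = math.floor(drop_fraction * n)
    # sort candidates by (weight asc, schema index desc): first n_drop go
    order = sorted(range(n), key=lambda i: (fused.fused[i], -i))
    drop_idx = set(order[:n_drop])
    retained = [fused.feature_names[i] for i in range(n) if i not in drop_idx]
    dropped = [fused.feature_names[i] for i in range(n) if i in drop_idx]
    return SelectionResult(
        retained=retained,
        dropped=dropped,
        drop_fraction=drop_fraction,
        fused=fused,
    )


def select_pipeline(
    table: FeatureTable,
    seed: int = 0,
    drop_fraction: float = 0.20,
) -> tuple[SelectionResult, FeatureTable]:
    """Run all three scorers on a labeled table, fuse, and drop the bottom fraction.

    Returns the selection result and the reduced table.
    """
    if table.labels is None:
        raise ValueError("feature selection requires a labeled table")
    names = list(table.feature_names)
    wr = rfe_weights(table.X, table.labels, names, seed=seed)
    we = tree_weights(table.X, table.labels, names, seed=seed)
    wm = mi_weights(table.X, table.labels, names, seed=seed)
    result = select_features(fuse_weights(wr, we, wm), drop_fraction)
    return result, table.subset_features(result.retained)


def weights_report(result: SelectionResult):
    """Per-feature report: components, fused weight, rank, retained flag."""
    import pandas as pd

    fused = result.fused
    rank = {
        name: r + 1
        for r, name in enumerate(
            sorted(
                fused.feature_names,
                key=lambda nm: -fused.fused[fused.feature_names.index(nm)],
            )
        )
    }
    retained = set(result.retained)
    rows = []
    for i, name in enumerate(fused.feature_names):
        rows.append(
            {
                "feature": name,
                "w_rfe": fused.components[SOURCE_RFE][i],
                "w_extra_trees": fused.components[SOURCE_TREES][i],
                "w_mutual_info": fused.components[SOURCE_MI][i],
                "w_fused": fused.fused[i],
                "rank": rank[name],
                "retained": name in retained,
            }
        )
    return pd.DataFrame(rows)
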