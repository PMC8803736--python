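"""SMOTE oversampling of the minority class.

For each synthetic sample, a minority point x_i is drawn uniformly, one of
its k nearest minority neighbors x_z (Euclidean, excluding itself) is drawn
uniformly, and the new point is x_i + u·(x_z − x_i) with u ~ Uniform(0,1) —
a random point on the segment between the two, hence inside the convex hull
of the minority class.  Original rows pass through unchanged; by default
enough synthetic points are added to equalize the class counts.

Balancing belongs strictly after the train/test split, on training data
only; oversampling before the split leaks synthetic copies of test
neighborhoods into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class SmoteConfig:
    """k-neighbor interpolation settings; ``ratio`` is the target
    minority/majority count ratio (1.0 = fully balanced)."""

    k_neighbors: int = 5
    ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.ratio <= 1.0:
            raise ValueError("ratio must be in (0, 1]")


def smote(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SmoteConfig | None = None,
    _u_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class; returns (X', y') with originals first.

    ``_u_override`` pins the interpolation coefficient (testing hook for the
    u=0 / u=1 endpoint contract).
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={cfg.k_neighbors}; "
            "use a smaller k"
        )
    n_new = int(round(cfg.ratio * n_maj)) - n_min
    if n_new <= 0:
        return X.copy(), y.copy()

    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xm)
    # column 0 is the point itself (distance 0); keep the k true neighbors
    neighbor_idx = nn.kneighbors(Xm, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(Xm), size=n_new)
    pick = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = (
        np.full(n_new, float(_u_override))
        if _u_override is not None
        else rng.uniform(0.0, 1.0, size=n_new)
    )
    xi = Xm[base]
    xz = Xm[neighbor_idx[base, pick]]
    synthetic = xi + u[:, None] * (xz - xi)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    assert (y_out == majority).sum() == n_maj
    return X_out, y_out
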