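"""SMOTE class balancing on the feature table.

The minority class is oversampled to parity by convex interpolation: each
synthetic row is x_i + u (x_nn - x_i) with u ~ Uniform(0, 1) and x_nn one
of the k nearest minority-class neighbours of x_i (Euclidean). Original
rows are never altered.

By default balancing is applied inside training folds only
(``within_train_folds``), which prevents synthetic points derived from test
windows from leaking into training; ``before_split`` reproduces global
balancing applied once before cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["BalanceConfig", "smote"]


@dataclass
class BalanceConfig:
    k_neighbors: int = 5
    seed: int = 0
    mode: str = "within_train_folds"  # or "before_split"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.mode not in ("within_train_folds", "before_split"):
            raise ValueError("mode must be 'within_train_folds' or 'before_split'")


def smote(
    X: np.ndarray, y: np.ndarray, config: BalanceConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample the minority class to parity.

    Returns (X', y', synthetic) where ``synthetic`` flags the appended rows.
    Already-balanced input is returned unchanged. Deterministic for a fixed
    ``config.seed``.
    """
    config = config or BalanceConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("smote expects exactly two classes")
    synthetic = np.zeros(y.size, dtype=bool)
    if counts[0] == counts[1]:
        return X.copy(), y.copy(), synthetic

    minority = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    Xmin = X[y == minority]
    if Xmin.shape[0] < config.k_neighbors + 1:
        raise ValueError(
            f"minority class has {Xmin.shape[0]} rows; needs "
            f">= k_neighbors + 1 = {config.k_neighbors + 1}"
        )
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself

    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, Xmin.shape[0], size=n_new)
    pick = rng.integers(1, config.k_neighbors + 1, size=n_new)
    u = rng.random(n_new)
    neighbours = Xmin[idx[base, pick]]
    new_rows = Xmin[base] + u[:, None] * (neighbours - Xmin[base])

    X_out = np.vstack([X, new_rows])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    synthetic = np.concatenate([synthetic, np.ones(n_new, dtype=bool)])
    return X_out, y_out, synthetic
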