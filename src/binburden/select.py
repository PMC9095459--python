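"""Random-forest feature weights and zero-importance pruning.

Bins are ranked by Gini impurity importance from a random forest (500
trees, sqrt(n_features) candidates per split, nodes grown until pure),
scaled so all bin weights sum to 1. Bins with exactly zero importance —
features never split on — are pruned from the feature matrix; the weights
themselves are reported as computed on the full bin set and are NOT
renormalized after pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = ["RFParams", "FeatureWeights", "compute_importances", "reduce_features"]


@dataclass(frozen=True)
class RFParams:
    """Forest settings: gini splits, sqrt feature sampling, pure leaves."""

    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")

    def to_estimator(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features="sqrt",
            min_samples_split=2,
            max_depth=None,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class FeatureWeights:
    """Per-bin importance weights, non-negative, summing to 1."""

    weights: np.ndarray
    bin_labels: list[str] = field(default_factory=list)
    category: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("negative weight")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.weights.sum()!r}, not 1")
        if self.bin_labels and len(self.bin_labels) != self.weights.shape[0]:
            raise ValueError("bin_labels length mismatch")

    def __len__(self) -> int:
        return self.weights.shape[0]

    def to_tsv(self, path) -> None:
        labels = self.bin_labels or [str(i) for i in range(len(self))]
        with open(path, "w") as fh:
            fh.write("bin\tweight\n")
            for lab, w in zip(labels, self.weights):
                fh.write(f"{lab}\t{w:.10g}\n")


def compute_importances(
    X: np.ndarray,
    y: np.ndarray,
    params: RFParams = RFParams(),
    bin_labels: list[str] | None = None,
    category: str | None = None,
) -> FeatureWeights:
    """Fit a random forest and return normalized impurity importances.

    Deterministic given ``params.seed``. Rejects single-class targets and
    non-finite features. If no split was ever made (degenerate data) the
    weights fall back to uniform so the sum-to-1 invariant holds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"X must be 2-D with >= 2 rows, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if np.unique(y).shape[0] < 2:
        raise ValueError("y must contain at least two classes")
    forest = params.to_estimator()
    with warnings.catch_warnings():
        # a label-powerset target legitimately has many classes
        warnings.filterwarnings("ignore", message=".*unique classes.*", category=UserWarning)
        forest.fit(X, y)
    imp = forest.feature_importances_
    total = imp.sum()
    weights = imp / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])
    return FeatureWeights(weights, bin_labels or [], category)


def reduce_features(
    X: np.ndarray, weights: FeatureWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Drop exactly the zero-weight bins; return (reduced X, kept ordinals).

    Column order of survivors is preserved and the kept-ordinal map allows
    hotspot reporting on the original bin coordinates. The comparison is an
    exact zero: impurity importance is exactly 0 for a feature no tree ever
    split on.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != len(weights):
        raise ValueError(f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, weights {len(weights)}")
    kept = np.flatnonzero(weights.weights != 0.0)
    return X[:, kept], kept
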