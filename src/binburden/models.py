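"""MLP classifiers for case-control and 8-way multi-label prediction.

Two prediction tasks share one estimator family (scikit-learn's
multilayer perceptron): a binary task separating individuals with any
diagnosed disorder from controls, and a multi-label task emitting a 1x8
binary vector over the eight disorders (ADHD, speech/language disorders,
developmental delays, depression, anxiety, ODD, autism, intellectual
disabilities — this column order is fixed). The multi-label network is a
single MLP with 8 sigmoid outputs thresholded at 0.5, not eight independent
binary models.

Hyperparameters (layers, neurons, activation, solver, L2 alpha, learning
rate, max iterations) are chosen by a budgeted seeded random search scored
on an inner validation split: the contract is "best configuration of the
budget", deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "DISORDER_LABELS",
    "PhenotypeMatrix",
    "MLPConfig",
    "SearchSpace",
    "FittedModel",
    "optimize_hyperparameters",
    "train_classifier",
    "predict_labels",
]

#: Fixed label order of the 8-column phenotype matrix.
DISORDER_LABELS: tuple[str, ...] = (
    "ADHD",
    "speech_language_disorders",
    "developmental_delays",
    "depression",
    "anxiety",
    "ODD",
    "autism",
    "intellectual_disabilities",
)


@dataclass
class PhenotypeMatrix:
    """Samples x 8 binary diagnosis labels in the fixed disorder order."""

    samples: list[str]
    Y: np.ndarray  # (n, 8) of {0, 1}

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if self.Y.shape != (len(self.samples), len(DISORDER_LABELS)):
            raise ValueError(f"Y shape {self.Y.shape} != ({len(self.samples)}, {len(DISORDER_LABELS)})")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("phenotype entries must be 0/1")

    @property
    def any_disorder(self) -> np.ndarray:
        """Binary case indicator: OR over the 8 label columns."""
        return (self.Y.sum(axis=1) > 0).astype(np.int8)

    @property
    def n_diagnoses(self) -> np.ndarray:
        return self.Y.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=self.samples, columns=list(DISORDER_LABELS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        missing = [c for c in DISORDER_LABELS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing label columns {missing}")
        return cls([str(s) for s in df.index], df[list(DISORDER_LABELS)].to_numpy())


@dataclass(frozen=True)
class MLPConfig:
    """One concrete MLP parameterization."""

    hidden_layer_sizes: tuple[int, ...] = (64,)
    activation: str = "relu"
    solver: str = "adam"
    alpha: float = 1e-4
    learning_rate_init: float = 1e-3
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layer_sizes or any(s < 1 for s in self.hidden_layer_sizes):
            raise ValueError(f"need >= 1 hidden layer of >= 1 neurons, got {self.hidden_layer_sizes}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")

    def to_estimator(self) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation=self.activation,
            solver=self.solver,
            alpha=self.alpha,
            learning_rate_init=self.learning_rate_init,
            max_iter=self.max_iter,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class SearchSpace:
    """Ranges for the tunables plus a search budget.

    Neuron counts, alpha and learning rate are sampled log-uniformly.
    """

    n_layers: tuple[int, int] = (1, 3)
    neurons: tuple[int, int] = (16, 256)
    activations: tuple[str, ...] = ("relu", "tanh", "logistic")
    solvers: tuple[str, ...] = ("adam", "lbfgs", "sgd")
    alpha: tuple[float, float] = (1e-6, 1e-1)
    max_iter: tuple[int, int] = (200, 2000)
    learning_rate_init: tuple[float, float] = (1e-4, 1e-1)
    budget: int = 30
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError(f"budget must be >= 1, got {self.budget}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")

    def sample(self, rng: np.random.Generator) -> MLPConfig:
        n_layers = int(rng.integers(self.n_layers[0], self.n_layers[1] + 1))
        sizes = tuple(
            int(round(math.exp(rng.uniform(math.log(self.neurons[0]), math.log(self.neurons[1])))))
            for _ in range(n_layers)
        )
        return MLPConfig(
            hidden_layer_sizes=sizes,
            activation=str(rng.choice(list(self.activations))),
            solver=str(rng.choice(list(self.solvers))),
            alpha=float(math.exp(rng.uniform(math.log(self.alpha[0]), math.log(self.alpha[1])))),
            learning_rate_init=float(
                math.exp(rng.uniform(math.log(self.learning_rate_init[0]), math.log(self.learning_rate_init[1])))
            ),
            max_iter=int(rng.integers(self.max_iter[0], self.max_iter[1] + 1)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )


@dataclass
class FittedModel:
    """A trained classifier handle; constant label columns are handled
    explicitly so prediction is always defined."""

    task: str  # "binary" | "multilabel"
    n_features: int
    estimator: MLPClassifier | None
    varying_cols: np.ndarray | None = None  # multilabel: columns the MLP models
    const_values: np.ndarray | None = None  # per-label constant, NaN where modelled
    kept_ordinals: np.ndarray | None = None  # original bin ordinals of the columns

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_labels(self, X)


def _score(task: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Inner-validation score: accuracy (binary) or 1 - hamming (multilabel)."""
    if task == "binary":
        return float(np.mean(y_true == y_pred))
    return 1.0 - float(np.mean(y_true != y_pred))


def optimize_hyperparameters(
    X_train: np.ndarray,
    y_train: np.ndarray,
    space: SearchSpace = SearchSpace(),
    task: str = "binary",
) -> MLPConfig:
    """Best-of-budget hyperparameter search on an inner validation split.

    Samples ``space.budget`` configurations with a seeded generator, trains
    each on the inner-train part, scores on the held-out inner-validation
    part, and returns the best scorer (first on ties). Deterministic given
    ``space.seed``. Configurations whose fit raises are skipped; if all
    fail the best partial cannot be formed and an error is raised.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    rng = np.random.default_rng(space.seed)
    n = X_train.shape[0]
    n_val = max(1, int(round(space.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("training set too small for an inner validation split")

    best: tuple[float, MLPConfig] | None = None
    for _ in range(space.budget):
        config = space.sample(rng)
        try:
            model = train_classifier(X_train[tr_idx], y_train[tr_idx], config, task)
            pred = model.predict(X_train[val_idx])
        except Exception as exc:  # noqa: BLE001 - skip failed candidates
            logger.warning("candidate %s failed: %s", config, exc)
            continue
        score = _score(task, y_train[val_idx], pred)
        if best is None or score > best[0]:
            best = (score, config)
    if best is None:
        raise RuntimeError("all hyperparameter candidates failed to fit")
    return best[1]


def train_classifier(
    X: np.ndarray,
    Y: np.ndarray,
    config: MLPConfig = MLPConfig(),
    task: str = "binary",
    kept_ordinals: np.ndarray | None = None,
) -> FittedModel:
    """Fit the MLP for one task.

    Binary: ``Y`` is a single 0/1 column (any-disorder vs control).
    Multilabel: ``Y`` is the samples x 8 label matrix; for the study design
    the caller restricts rows to patients with >= 1 diagnosis. Label
    columns constant in training are warned about and predicted constant.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if task == "binary":
        y = Y.ravel()
        if np.unique(y).shape[0] < 2:
            logger.warning("binary target is constant; model collapses to that class")
            return FittedModel("binary", X.shape[1], None, const_values=np.array([y[0]]),
                               kept_ordinals=kept_ordinals)
        est = config.to_estimator()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        return FittedModel("binary", X.shape[1], est, kept_ordinals=kept_ordinals)
    if task != "multilabel":
        raise ValueError(f"unknown task {task!r}")
    if Y.ndim != 2:
        raise ValueError("multilabel Y must be 2-D")
    n_labels = Y.shape[1]
    varying = np.flatnonzero(Y.min(axis=0) != Y.max(axis=0))
    const_values = np.full(n_labels, np.nan)
    for j in range(n_labels):
        if j not in varying:
            logger.warning("label column %d constant in training; predicted constant", j)
            const_values[j] = Y[0, j]
    est = None
    if varying.size:
        est = config.to_estimator()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if varying.size == 1:
                est.fit(X, Y[:, varying[0]])
            else:
                est.fit(X, Y[:, varying])
    return FittedModel("multilabel", X.shape[1], est, varying_cols=varying,
                       const_values=const_values, kept_ordinals=kept_ordinals)


def predict_labels(model: FittedModel, X_test: np.ndarray) -> np.ndarray:
    """Hard 0/1 predictions; multi-label outputs threshold each of the 8
    sigmoid outputs at 0.5 independently (no any-disorder consistency is
    enforced across columns)."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.ndim != 2 or X_test.shape[1] != model.n_features:
        raise ValueError(
            f"X_test has {X_test.shape[1] if X_test.ndim == 2 else '?'} columns; "
            f"model was trained on {model.n_features}"
        )
    m = X_test.shape[0]
    if model.task == "binary":
        if m == 0:
            return np.zeros(0, dtype=np.int8)
        if model.estimator is None:
            return np.full(m, int(model.const_values[0]), dtype=np.int8)
        return model.estimator.predict(X_test).astype(np.int8)
    n_labels = model.const_values.shape[0]
    out = np.zeros((m, n_labels), dtype=np.int8)
    if m == 0:
        return out
    for j in range(n_labels):
        if not np.isnan(model.const_values[j]):
            out[:, j] = int(model.const_values[j])
    if model.estimator is not None and model.varying_cols.size:
        pred = model.estimator.predict(X_test)
        if model.varying_cols.size == 1:
            out[:, model.varying_cols[0]] = pred.astype(np.int8)
        else:
            out[:, model.varying_cols] = pred.astype(np.int8)
    return out
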