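"""Shuffle-test evaluation protocol and multi-label metrics.

The predictive ability of each variant category's burden features is
assessed by repeated random two-fold tests: the eligible cohort is split
1:1 (up to one sample), feature selection and model training happen on the
first fold only, predictions are scored on the second, and the per-round
metrics are summarized as mean +- sample SD over rounds (default 50).

Metrics: plain accuracy for the binary tasks; hamming loss (fraction of
the 8 x m label cells predicted incorrectly), exact-match rate (fraction of
samples whose whole 8-label vector is correct; chance level for uniform
random guessing is (1/2)^8 = 1/256), and per-label precision/recall for
the multi-label task. A precision or recall with a zero denominator is
reported as 0 and flagged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .models import (
    DISORDER_LABELS,
    MLPConfig,
    PhenotypeMatrix,
    SearchSpace,
    optimize_hyperparameters,
    predict_labels,
    train_classifier,
)
from .select import RFParams, compute_importances, reduce_features

__all__ = [
    "hamming_loss",
    "exact_match_rate",
    "per_label_precision_recall",
    "ShuffleProtocol",
    "PipelineSpec",
    "EvaluationReport",
    "two_fold_shuffle",
    "powerset_encode",
]

TASKS = ("case_control", "single_diagnosis_vs_control", "multilabel")


def _check_pair(Y_true: np.ndarray, Y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y_true = np.asarray(Y_true)
    Y_pred = np.asarray(Y_pred)
    if Y_true.shape != Y_pred.shape:
        raise ValueError(f"shape mismatch: {Y_true.shape} vs {Y_pred.shape}")
    for name, Y in (("Y_true", Y_true), ("Y_pred", Y_pred)):
        if not np.isin(Y, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return Y_true, Y_pred


def hamming_loss(Y_true: np.ndarray, Y_pred: np.ndarray) -> float:
    """Fraction of label cells predicted incorrectly; 0 perfect, 1 all wrong."""
    Y_true, Y_pred = _check_pair(Y_true, Y_pred)
    return float(np.mean(Y_true != Y_pred))


def exact_match_rate(Y_true: np.ndarray, Y_pred: np.ndarray) -> float:
    """Fraction of samples whose entire label vector is predicted exactly."""
    Y_true, Y_pred = _check_pair(Y_true, Y_pred)
    if Y_true.ndim == 1:
        Y_true = Y_true[:, None]
        Y_pred = Y_pred[:, None]
    return float(np.mean((Y_true == Y_pred).all(axis=1)))


def per_label_precision_recall(
    Y_true: np.ndarray, Y_pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column precision TP/(TP+FP) and recall TP/(TP+FN).

    Returns (precision, recall, precision_undefined, recall_undefined);
    a zero-denominator metric is reported as 0 with its flag set.
    """
    Y_true, Y_pred = _check_pair(Y_true, Y_pred)
    tp = ((Y_true == 1) & (Y_pred == 1)).sum(axis=0).astype(float)
    fp = ((Y_true == 0) & (Y_pred == 1)).sum(axis=0).astype(float)
    fn = ((Y_true == 1) & (Y_pred == 0)).sum(axis=0).astype(float)
    p_undef = (tp + fp) == 0
    r_undef = (tp + fn) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(p_undef, 0.0, tp / np.where(p_undef, 1.0, tp + fp))
        recall = np.where(r_undef, 0.0, tp / np.where(r_undef, 1.0, tp + fn))
    return precision, recall, p_undef, r_undef


def powerset_encode(Y: np.ndarray) -> np.ndarray:
    """Encode a multi-label matrix as one class per distinct label pattern
    (label powerset; up to 2^8 = 256 classes), used as the random-forest
    target when selecting features for the multi-label task."""
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D")
    powers = 1 << np.arange(Y.shape[1])
    return (Y.astype(np.int64) * powers).sum(axis=1)


@dataclass(frozen=True)
class ShuffleProtocol:
    """Repeated random 1:1 split settings for one task."""

    task: str = "case_control"
    n_rounds: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.n_rounds < 1:
            raise ValueError(f"n_rounds must be >= 1, got {self.n_rounds}")


@dataclass(frozen=True)
class PipelineSpec:
    """Per-round pipeline: RF feature selection + MLP (fixed or searched).

    If ``search_space`` is given, hyperparameters are optimized on the first
    round's training fold and reused thereafter unless
    ``reoptimize_per_round`` is set.
    """

    rf_params: RFParams = RFParams()
    mlp_config: MLPConfig = MLPConfig()
    search_space: SearchSpace | None = None
    reoptimize_per_round: bool = False


@dataclass
class EvaluationReport:
    """Per-round metric values with mean and sample SD (ddof=1)."""

    task: str
    metrics: dict[str, list[float]]
    round_seeds: list[int]
    precision_rounds: list[np.ndarray] = field(default_factory=list)
    recall_rounds: list[np.ndarray] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean(self.metrics[metric]))

    def sd(self, metric: str) -> float:
        vals = self.metrics[metric]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def per_label_summary(self) -> pd.DataFrame:
        """Mean +- SD precision/recall per disorder over rounds."""
        P = np.vstack(self.precision_rounds)
        R = np.vstack(self.recall_rounds)
        ddof = 1 if P.shape[0] > 1 else 0
        return pd.DataFrame(
            {
                "precision_mean": P.mean(axis=0),
                "precision_sd": P.std(axis=0, ddof=ddof),
                "recall_mean": R.mean(axis=0),
                "recall_sd": R.std(axis=0, ddof=ddof),
            },
            index=list(DISORDER_LABELS),
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, self.mean(m), self.sd(m)) for m in self.metrics],
            columns=["metric", "mean", "sd"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)

    def rounds_frame(self) -> pd.DataFrame:
        rows = []
        for m, vals in self.metrics.items():
            for r, v in enumerate(vals):
                rows.append((r, self.round_seeds[r], m, v))
        return pd.DataFrame(rows, columns=["round", "seed", "metric", "value"])


def _eligible(task: str, phen: PhenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row mask and target for one task.

    case_control: everyone, any-disorder indicator. single_diagnosis_vs_control:
    cases with exactly one diagnosis plus all controls. multilabel: the
    >= 1-diagnosis patients only, 8-column target.
    """
    n_diag = phen.n_diagnoses
    if task == "case_control":
        return np.ones(len(phen.samples), dtype=bool), phen.any_disorder
    if task == "single_diagnosis_vs_control":
        mask = (n_diag <= 1)
        return mask, phen.any_disorder[mask]
    mask = n_diag >= 1
    return mask, phen.Y[mask]


def two_fold_shuffle(
    X: np.ndarray,
    phenotypes: PhenotypeMatrix,
    protocol: ShuffleProtocol,
    pipeline: PipelineSpec = PipelineSpec(),
    progress: Callable[[int], None] | None = None,
) -> EvaluationReport:
    """Run the repeated two-fold shuffle test for one burden matrix.

    Each round r: split the eligible samples 1:1 with seed ``base_seed + r``;
    compute RF importances and prune zero-weight bins on the training fold
    only; train the MLP on the training fold; score hard predictions on the
    held-out fold. Test samples never influence feature selection or
    hyperparameter search. A round whose training fold lacks both classes
    is resampled once, then the run fails.
    """
    X = np.asarray(X, dtype=float)
    mask, target = _eligible(protocol.task, phenotypes)
    Xe = X[mask]
    n = Xe.shape[0]
    if n < 4:
        raise ValueError(f"only {n} eligible samples for task {protocol.task!r}")
    binary = protocol.task != "multilabel"
    if binary and np.unique(target).shape[0] < 2:
        raise ValueError(f"task {protocol.task!r} needs both classes among eligible samples")

    metrics: dict[str, list[float]] = (
        {"accuracy": []} if binary else {"hamming_loss": [], "exact_match_rate": [], "accuracy_per_cell": []}
    )
    report = EvaluationReport(protocol.task, metrics, [])
    chosen_config: MLPConfig | None = None if pipeline.search_space is not None else pipeline.mlp_config

    n_train = n // 2
    for r in range(protocol.n_rounds):
        seed = protocol.base_seed + r
        rng = np.random.default_rng(seed)
        for attempt in range(2):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            y_tr = target[tr]
            ok = (np.unique(y_tr).shape[0] >= 2) if binary else bool(powerset_encode(target[tr]).std() > 0)
            if ok:
                break
        else:
            raise RuntimeError(f"round {r}: training fold lacks class variation after resampling")
        report.round_seeds.append(seed)

        sel_y = y_tr if binary else powerset_encode(target[tr])
        rf = dataclasses.replace(pipeline.rf_params, seed=pipeline.rf_params.seed + r)
        weights = compute_importances(Xe[tr], sel_y, rf)
        X_tr, kept = reduce_features(Xe[tr], weights)
        X_te = Xe[te][:, kept]

        task = "binary" if binary else "multilabel"
        if chosen_config is None or (pipeline.search_space is not None and pipeline.reoptimize_per_round):
            space = dataclasses.replace(pipeline.search_space, seed=pipeline.search_space.seed + (r if pipeline.reoptimize_per_round else 0))
            chosen_config = optimize_hyperparameters(X_tr, y_tr if binary else target[tr], space, task)
        config = dataclasses.replace(chosen_config, seed=chosen_config.seed + r)
        model = train_classifier(X_tr, y_tr if binary else target[tr], config, task, kept_ordinals=kept)
        pred = predict_labels(model, X_te)

        if binary:
            metrics["accuracy"].append(float(np.mean(pred == target[te])))
        else:
            Y_te = target[te]
            hl = hamming_loss(Y_te, pred)
            metrics["hamming_loss"].append(hl)
            metrics["exact_match_rate"].append(exact_match_rate(Y_te, pred))
            metrics["accuracy_per_cell"].append(1.0 - hl)
            p, rc, _, _ = per_label_precision_recall(Y_te, pred)
            report.precision_rounds.append(p)
            report.recall_rounds.append(rc)
        if progress is not None:
            progress(r)
    return report
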