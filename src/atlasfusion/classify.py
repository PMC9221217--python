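"""RBF-SVM classification under nested leave-one-out cross-validation.

The outer LOOCV loop estimates generalization: for every held-out subject,
feature selection (MRMR + SFC) and hyperparameter tuning (grid search over C
and the RBF width gamma, scored by inner LOOCV) run on the remaining
subjects only, a final SVM is trained on them, and the held-out subject is
predicted once.  Out-of-fold predictions aggregate into accuracy,
sensitivity (patient class), specificity (control class) and trapezoidal
AUC over the decision values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from . import _svm
from .exceptions import PipelineError
from .selection import FeatureTable, SelectionResult, mrmr_rank, sfc_search

logger = logging.getLogger(__name__)

__all__ = [
    "default_grid",
    "ClassifierConfig",
    "SelectionConfig",
    "Metrics",
    "CVResult",
    "grid_search",
    "inner_loocv_accuracy",
    "nested_loocv",
    "compute_metrics",
]


def default_grid() -> np.ndarray:
    """The C / gamma ladder 2^-8, 2^-7.5, ..., 2^8 (33 values)."""
    return 2.0 ** np.arange(-8.0, 8.25, 0.5)


@dataclass
class ClassifierConfig:
    """SVM kernel, hyperparameter grids and SFC evaluator policy.

    ``sfc_hyperparams`` controls how each SFC window is scored: ``"grid"``
    re-runs the full grid search per window (faithful but slow); a
    ``(C, gamma)`` pair scores every window with those fixed values and
    leaves the grid search to the chosen window only (fast mode).
    """

    kernel: str = "rbf"
    c_grid: np.ndarray = field(default_factory=default_grid)
    gamma_grid: np.ndarray = field(default_factory=default_grid)
    tol: float = 1e-3
    sfc_hyperparams: object = "grid"

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        for grid in (self.c_grid, self.gamma_grid):
            if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
                raise ValueError("grids must be positive and strictly increasing")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")


@dataclass
class SelectionConfig:
    """MRMR + SFC selection settings used inside each outer training fold."""

    mrmr_k: int = 50
    n_bins: int = 5


def inner_loocv_accuracy(
    x: np.ndarray, y: np.ndarray, C: float, gamma: float, config: ClassifierConfig
) -> float:
    """Inner-LOOCV accuracy at one (C, gamma) point (per-fold z-scoring)."""
    return _svm.loocv_accuracy(
        x, y, C=C, gamma=gamma, kernel=config.kernel, tol=config.tol
    )


def grid_search(
    x: np.ndarray, y: np.ndarray, config: ClassifierConfig
) -> tuple[float, float, float]:
    """Pick (C, gamma) maximizing inner-LOOCV accuracy on the training data.

    Ties break to the smallest C, then the smallest gamma (regularization
    parsimony).  Returns ``(C, gamma, inner_accuracy)``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes in the training data")
    best: tuple[float, float, float] | None = None
    for c_val in config.c_grid:
        for g_val in config.gamma_grid:
            acc = inner_loocv_accuracy(x, y, c_val, g_val, config)
            if best is None or acc > best[2] + 1e-12:
                best = (float(c_val), float(g_val), acc)
    assert best is not None
    return best


def _window_evaluator(table: FeatureTable, config: ClassifierConfig):
    """Evaluator used by SFC: inner-LOOCV accuracy of a feature subset."""
    x_all = table.values
    y = table.labels.astype(float)

    if config.sfc_hyperparams == "grid":

        def evaluate(subset: list) -> float:
            return grid_search(x_all[:, subset], y, config)[2]

    else:
        c_fix, g_fix = config.sfc_hyperparams

        def evaluate(subset: list) -> float:
            return inner_loocv_accuracy(x_all[:, subset], y, c_fix, g_fix, config)

    return evaluate


def select_features(
    table: FeatureTable, config: ClassifierConfig, selection: SelectionConfig
) -> SelectionResult:
    """MRMR ranking then SFC window search, all on the given (training) table."""
    ranked = mrmr_rank(table, k=selection.mrmr_k, n_bins=selection.n_bins)
    return sfc_search(ranked, _window_evaluator(table, config))


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


@dataclass
class CVResult:
    """Per-subject out-of-fold predictions plus derived metrics."""

    truth: np.ndarray
    predictions: np.ndarray
    decision_values: np.ndarray | None
    fold_details: list
    metrics: Metrics
    roc: tuple | None = None

    @property
    def fold_window_sizes(self) -> list:
        return [d["n_selected"] for d in self.fold_details if "n_selected" in d]

    @property
    def n_selected_mode(self) -> int | None:
        """Most common per-fold window size (the headline feature count)."""
        sizes = self.fold_window_sizes
        if not sizes:
            return None
        values, counts = np.unique(sizes, return_counts=True)
        return int(values[np.argmax(counts)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "truth": self.truth.astype(int).tolist(),
            "predictions": self.predictions.astype(int).tolist(),
            "decision_values": (
                None
                if self.decision_values is None
                else [float(v) for v in self.decision_values]
            ),
            "fold_details": self.fold_details,
            "metrics": self.metrics.as_dict(),
            "n_selected_mode": self.n_selected_mode,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def compute_metrics(
    truth: Sequence[int],
    predictions: Sequence[int],
    decision_values: Sequence[float] | None = None,
) -> tuple[Metrics, tuple | None]:
    """Confusion-table metrics plus trapezoidal ROC/AUC.

    The patient group is coded 1 (positive).  Sensitivity is the correct
    rate over patients, specificity over controls.  AUC integrates the
    empirical ROC of the decision values with the trapezoidal rule and is
    ``None`` when no decision values exist (e.g. hard majority votes).
    """
    truth = np.asarray(truth, dtype=int).ravel()
    predictions = np.asarray(predictions, dtype=int).ravel()
    if truth.size != predictions.size:
        raise ValueError("truth and predictions must have equal length")
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics undefined: one class absent from the truth")
    tp = int(((truth == 1) & (predictions == 1)).sum())
    tn = int(((truth == 0) & (predictions == 0)).sum())
    metrics = Metrics(
        accuracy=(tp + tn) / truth.size,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
    )
    roc = None
    if decision_values is not None:
        decision_values = np.asarray(decision_values, dtype=float).ravel()
        fpr, tpr, _ = roc_curve(truth, decision_values)
        metrics.auc = float(_trapezoid_auc(fpr, tpr))
        roc = (fpr, tpr)
    return metrics, roc


def _zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def nested_loocv(
    table: FeatureTable,
    config: ClassifierConfig | None = None,
    selection: SelectionConfig | None = None,
) -> CVResult:
    """Nested LOOCV: selection and tuning strictly inside each outer fold.

    Parameters
    ----------
    table : FeatureTable
    config : ClassifierConfig, optional
        Defaults to an RBF kernel with the full 33x33 grid.
    selection : SelectionConfig, optional
        When given, MRMR + SFC run on each outer training fold; when None the
        fold uses all features (no selection).

    Returns
    -------
    CVResult with out-of-fold predictions, signed decision values from each
    outer-fold model, per-fold chosen (C, gamma) and selection window, and
    aggregate metrics.
    """
    config = config or ClassifierConfig()
    n = table.n_subjects
    if n < 10:
        raise ValueError("nested LOOCV needs at least 10 subjects")
    truth = table.labels.astype(int)
    predictions = np.full(n, -1, dtype=int)
    decisions = np.full(n, np.nan)
    fold_details: list[dict] = []
    skipped: list[int] = []
    all_idx = np.arange(n)
    for i in range(n):
        train_idx = all_idx[all_idx != i]
        y_train = truth[train_idx]
        if len(np.unique(y_train)) < 2:
            logger.error("fold %d skipped: training set is single-class", i)
            skipped.append(i)
            continue
        train_table = FeatureTable(
            values=table.values[train_idx],
            labels=y_train,
            feature_names=list(table.feature_names),
            feature_meta=list(table.feature_meta),
            subject_ids=[table.subject_ids[j] for j in train_idx],
        )
        detail: dict = {"held_out": int(i)}
        if selection is not None:
            sel = select_features(train_table, config, selection)
            cols = sel.selected_ids
            detail["window"] = [int(sel.window[0]), int(sel.window[1])]
            detail["n_selected"] = int(sel.n_selected)
        else:
            cols = list(range(table.n_features))
        x_train = table.values[np.ix_(train_idx, cols)]
        c_best, g_best, inner_acc = grid_search(x_train, y_train, config)
        detail.update(C=c_best, gamma=g_best, inner_accuracy=inner_acc)
        mu, sd = _zscore_fit(x_train)
        clf = SVC(kernel=config.kernel, C=c_best, gamma=g_best, tol=config.tol)
        clf.fit((x_train - mu) / sd, y_train)
        x_test = (table.values[i, cols] - mu) / sd
        predictions[i] = int(clf.predict(x_test[None, :])[0])
        decisions[i] = float(clf.decision_function(x_test[None, :])[0])
        fold_details.append(detail)
    done = predictions >= 0
    if not np.any(done):
        raise PipelineError("every outer fold was skipped")
    metrics, roc = compute_metrics(truth[done], predictions[done], decisions[done])
    return CVResult(
        truth=truth[done],
        predictions=predictions[done],
        decision_values=decisions[done],
        fold_details=fold_details,
        metrics=metrics,
        roc=roc,
    )
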