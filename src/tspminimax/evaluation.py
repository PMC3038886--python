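"""Leave-one-out cross-validation driver and cohort summaries.

Each fold re-runs pair selection on the N-1 training samples only, so the
held-out sample never influences its own feature space.  Summaries count
confidently predictable (CP) patients, errors among them, and total errors.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .expression_io import ExpressionDataset
from .knn_baseline import KnnPrediction, knn_predict
from .local_minimax import (
    MinimaxConfig,
    Prediction,
    estimate,
    is_confidently_predictable,
)
from .tsp_features import TSPModel, feature_matrix, select_top_k_disjoint, transform


class EvaluationError(ValueError):
    """Raised when a cross-validation fold cannot be evaluated."""


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level counts with exactly recomputable percentages.

    ``error_in_cp_percent`` is None (rendered as an em dash) when no patient
    is confidently predictable.
    """

    n: int
    cp_count: int
    errors_in_cp: int
    total_errors: int
    config: dict

    def __post_init__(self) -> None:
        if not 0 <= self.errors_in_cp <= self.cp_count <= self.n:
            raise ValueError("inconsistent CP counts")
        if not 0 <= self.total_errors <= self.n:
            raise ValueError("inconsistent total error count")

    @property
    def cp_percent(self) -> float:
        return 100.0 * self.cp_count / self.n

    @property
    def error_in_cp_percent(self) -> float | None:
        if self.cp_count == 0:
            return None
        return 100.0 * self.errors_in_cp / self.cp_count

    @property
    def total_error_percent(self) -> float:
        return 100.0 * self.total_errors / self.n

    def to_dict(self) -> dict:
        e = self.error_in_cp_percent
        return {
            "n": self.n,
            "cp_count": self.cp_count,
            "cp_percent": self.cp_percent,
            "errors_in_cp": self.errors_in_cp,
            "error_in_cp_percent": e,
            "total_errors": self.total_errors,
            "total_error_percent": self.total_error_percent,
            "config": dict(self.config),
        }

    def format_row(self) -> str:
        e = self.error_in_cp_percent
        e_str = "—" if e is None else f"{e:.2f}%"
        return (
            f"n={self.n}  CP={self.cp_count} ({self.cp_percent:.1f}%)  "
            f"error in CP={self.errors_in_cp} ({e_str})  "
            f"total errors={self.total_errors} ({self.total_error_percent:.2f}%)"
        )


@dataclass(frozen=True)
class PatientResult:
    sample_id: str
    prediction: Prediction | KnnPrediction
    true_label: int


@dataclass(frozen=True)
class SigmaSweepCurve:
    """Cohort-level LOOCV summaries over a grid of bandwidth fractions."""

    fractions: tuple[float, ...]
    summaries: tuple[CohortSummary, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.summaries):
            raise ValueError("one summary per grid point required")


@dataclass(frozen=True)
class _Fold:
    sample_id: str
    true_label: int
    model: TSPModel
    train_features: np.ndarray
    train_labels: np.ndarray
    query_features: np.ndarray


def _build_folds(dataset: ExpressionDataset, k: int) -> list[_Fold]:
    if dataset.labels is None:
        raise EvaluationError("dataset has no labels")
    N = dataset.n_samples
    folds: list[_Fold] = []
    for j in range(N):
        sid = dataset.sample_ids[j]
        train_idx = [m for m in range(N) if m != j]
        train_labels = dataset.labels[train_idx]
        if len(set(train_labels.tolist())) < 2:
            raise EvaluationError(
                f"fold for sample {sid!r}: training set contains a single class"
            )
        sub = dataset.subset_samples(train_idx)
        model = select_top_k_disjoint(sub, k)
        feats = feature_matrix(sub, model).vectors
        query = transform(dataset.sample_profile(sid), model)
        folds.append(
            _Fold(
                sample_id=sid,
                true_label=int(dataset.labels[j]),
                model=model,
                train_features=feats,
                train_labels=train_labels,
                query_features=query,
            )
        )
    return folds


def _predict_fold(fold: _Fold, config: MinimaxConfig, method: str):
    if method == "kernel":
        return estimate(
            fold.query_features, fold.train_features, fold.train_labels, config
        )
    if method == "knn":
        return knn_predict(fold.query_features, fold.train_features, fold.train_labels)
    raise ValueError(f"unknown method {method!r}")


def loocv(
    dataset: ExpressionDataset,
    config: MinimaxConfig,
    method: str = "kernel",
    progress: bool = False,
) -> tuple[list[PatientResult], CohortSummary]:
    """Leave-one-out evaluation with per-fold feature re-selection."""
    folds = _build_folds(dataset, config.k)
    results: list[PatientResult] = []
    for idx, fold in enumerate(folds):
        pred = _predict_fold(fold, config, method)
        results.append(PatientResult(fold.sample_id, pred, fold.true_label))
        if progress:
            print(
                f"fold {idx + 1}/{len(folds)}: {fold.sample_id}",
                file=sys.stderr,
            )
    summary = summarize(
        [(r.prediction, r.true_label) for r in results],
        config.p_threshold,
        config=config.snapshot(),
    )
    return results, summary


def summarize(
    predictions: Sequence[tuple[object, int]],
    p_threshold: float,
    config: dict | None = None,
) -> CohortSummary:
    """Count CP patients, CP errors and total errors from per-patient results.

    Kernel predictions are re-thresholded from their stored interval at
    ``p_threshold``; baseline predictions carry their own CP flag.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("cannot summarize an empty prediction list")
    cp = 0
    cp_err = 0
    total_err = 0
    for pred, truth in predictions:
        if hasattr(pred, "ci_low"):
            is_cp = is_confidently_predictable(
                (pred.ci_low, pred.ci_high), p_threshold
            )
        else:
            is_cp = bool(pred.cp_flag)
        wrong = int(pred.class_call) != int(truth)
        cp += is_cp
        cp_err += is_cp and wrong
        total_err += wrong
    return CohortSummary(
        n=len(predictions),
        cp_count=cp,
        errors_in_cp=cp_err,
        total_errors=total_err,
        config=config or {"p_threshold": p_threshold},
    )


def cohort_sigma_sweep(
    dataset: ExpressionDataset,
    config: MinimaxConfig,
    fractions: Sequence[float],
) -> SigmaSweepCurve:
    """LOOCV summaries per bandwidth fraction; selection runs once per fold.

    Pair selection does not depend on the bandwidth, so each fold's feature
    space is shared across the whole grid.
    """
    fractions = [float(f) for f in fractions]
    if not fractions:
        raise ValueError("fraction grid must be non-empty")
    folds = _build_folds(dataset, config.k)
    summaries = []
    for frac in fractions:
        cfg = replace(config, sigma_fraction=frac)
        pairs = []
        for fold in folds:
            pred = _predict_fold(fold, cfg, "kernel")
            pairs.append((pred, fold.true_label))
        summaries.append(
            summarize(pairs, cfg.p_threshold, config=cfg.snapshot())
        )
    return SigmaSweepCurve(fractions=tuple(fractions), summaries=tuple(summaries))
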