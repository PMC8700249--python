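"""Discriminant-analysis grading classifier under stratified k-fold CV.

Linear discriminant analysis (shared covariance, empirical class priors) is
deliberately tolerant of the ~70/30 high/low-grade imbalance, which is why
it is the classifier of this workflow. Folds are stratified so every
training and validation split keeps the cohort's grade proportions.

Metric conventions (low grade is the positive class):

* sensitivity = correctly identified low-grade / all low-grade,
* specificity = correctly identified high-grade / all high-grade,
* accuracy    = all correct / all,
* AUC on the pooled out-of-fold scores (posterior probability of low
  grade), with a 95% Wald interval from the Hanley–McNeil standard error.
  The interval is reported unclipped and may exceed [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .selection import SelectionResult, sequential_select

logger = logging.getLogger(__name__)

__all__ = [
    "CvConfig",
    "EvaluationReport",
    "lda_fit",
    "stratified_kfold",
    "evaluate",
    "hanley_mcneil_se",
]


@dataclass(frozen=True)
class CvConfig:
    k: int = 5
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


@dataclass
class FoldMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    tp_low: int
    fn_low: int
    tn_high: int
    fp_high: int


@dataclass
class EvaluationReport:
    """Per-fold and aggregate CV performance."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    auc_ci: tuple[float, float]
    pooled_sensitivity: float
    pooled_specificity: float
    pooled_accuracy: float
    confusion: dict[str, int]
    fold_metrics: list[FoldMetrics]
    n_low: int
    n_high: int
    selected_features: list[str]
    selection_mode: str
    cv: CvConfig = field(default_factory=CvConfig)
    warnings: list[str] = field(default_factory=list)
    pooled_scores: np.ndarray | None = None
    pooled_labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "auc_ci95": list(self.auc_ci),
            "pooled": {
                "sensitivity": self.pooled_sensitivity,
                "specificity": self.pooled_specificity,
                "accuracy": self.pooled_accuracy,
                "confusion": self.confusion,
            },
            "n_low": self.n_low,
            "n_high": self.n_high,
            "selected_features": self.selected_features,
            "selection_mode": self.selection_mode,
            "cv": {"k": self.cv.k, "n_repeats": self.cv.n_repeats, "seed": self.cv.seed},
            "warnings": self.warnings,
        }

    def summary(self) -> str:
        lo, hi = self.auc_ci
        return (
            f"sensitivity {self.sensitivity:.2%}  specificity {self.specificity:.2%}  "
            f"accuracy {self.accuracy:.2%}  AUC {self.auc:.2%} "
            f"(95% CI {lo:.2%}-{hi:.2%}, unclipped)  "
            f"[{self.n_low} low / {self.n_high} high; k={self.cv.k}; "
            f"features: {', '.join(self.selected_features)}; mode={self.selection_mode}]"
        )


def lda_fit(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    """Fit a linear discriminant model with empirical class priors.

    Falls back to a ridge-style shrinkage solver if the pooled covariance is
    singular for the default SVD solver.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training set needs at least 2 samples of each class")
    try:
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X, y)
    except (np.linalg.LinAlgError, IndexError, FloatingPointError):
        # degenerate pooled covariance; shrinkage keeps the fit defined
        logger.warning("singular pooled covariance; refitting with shrinkage (lsqr)")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X, y)
    return clf


def low_grade_score(clf: LinearDiscriminantAnalysis, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the low-grade (0) class."""
    i0 = int(np.flatnonzero(clf.classes_ == 0)[0])
    return clf.predict_proba(np.asarray(X, dtype=np.float64))[:, i0]


def stratified_kfold(
    labels: np.ndarray, config: CvConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded, stratified fold assignments as (train, test) index pairs."""
    y = np.asarray(labels)
    minority = int(np.unique(y, return_counts=True)[1].min())
    if config.k > minority:
        raise ValueError(
            f"k={config.k} exceeds the minority class count ({minority}); use a smaller k"
        )
    skf = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=config.seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of a ROC AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> FoldMetrics:
    low = y_true == 0
    high = y_true == 1
    tp = int((y_pred[low] == 0).sum())
    fn = int(low.sum()) - tp
    tn = int((y_pred[high] == 1).sum())
    fp = int(high.sum()) - tn
    return FoldMetrics(
        sensitivity=tp / low.sum() if low.any() else np.nan,
        specificity=tn / high.sum() if high.any() else np.nan,
        accuracy=float((y_pred == y_true).mean()),
        tp_low=tp,
        fn_low=fn,
        tn_high=tn,
        fp_high=fp,
    )


def evaluate(
    table: pd.DataFrame,
    selected: list[str] | None,
    config: CvConfig = CvConfig(),
    label_column: str = "grade",
    selection_mode: str = "cumulative",
    nested_selection: bool = False,
) -> EvaluationReport:
    """Cross-validated LDA evaluation of a feature table.

    With ``nested_selection=True`` the sequential feature selection is rerun
    inside every training fold (leak-free mode) and ``selected`` only
    defines the candidate pool (``None`` = all feature columns). With
    ``nested_selection=False`` the model uses exactly ``selected``, which
    must then be nonempty — this mirrors running selection once on the full
    table before CV.
    """
    from .features.table import METADATA_COLUMNS

    y = table[label_column].to_numpy(dtype=int)
    if selected:
        candidates = [c for c in selected if c in table.columns]
    else:
        skip = set(METADATA_COLUMNS) | {label_column}
        candidates = [
            c
            for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    if not candidates:
        raise ValueError("no usable feature columns")
    if not nested_selection and not selected:
        raise ValueError("fixed-feature evaluation needs a nonempty selected list")

    all_warnings: list[str] = []
    fold_metrics: list[FoldMetrics] = []
    repeat_aucs: list[float] = []
    pooled_scores = np.full(len(y), np.nan)
    pooled_pred = np.full(len(y), -1)
    used_features: list[str] = list(candidates)

    for rep in range(config.n_repeats):
        rep_cfg = CvConfig(k=config.k, n_repeats=1, seed=config.seed + rep)
        folds = stratified_kfold(y, rep_cfg)
        rep_scores = np.full(len(y), np.nan)
        for tr, te in folds:
            feats = candidates
            if nested_selection:
                sel: SelectionResult = sequential_select(
                    table.iloc[tr][candidates], y[tr], mode=selection_mode
                )
                feats = sel.selected
                all_warnings.extend(sel.warnings)
                used_features = feats  # last fold's choice, reported for reference
            Xtr = table.iloc[tr][feats].to_numpy(dtype=np.float64)
            Xte = table.iloc[te][feats].to_numpy(dtype=np.float64)
            clf = lda_fit(Xtr, y[tr])
            pred = clf.predict(Xte)
            score = low_grade_score(clf, Xte)
            rep_scores[te] = score
            if rep == 0:
                pooled_scores[te] = score
                pooled_pred[te] = pred
                fold_metrics.append(_fold_metrics(y[te], pred))
        # low grade is the positive class; its score is P(low)
        repeat_aucs.append(float(roc_auc_score((y == 0).astype(int), rep_scores)))

    n_low = int((y == 0).sum())
    n_high = int((y == 1).sum())
    auc = float(np.mean(repeat_aucs))
    se = hanley_mcneil_se(auc, n_low, n_high)
    ci = (auc - 1.96 * se, auc + 1.96 * se)
    pooled = _fold_metrics(y, pooled_pred)
    return EvaluationReport(
        sensitivity=float(np.mean([m.sensitivity for m in fold_metrics])),
        specificity=float(np.mean([m.specificity for m in fold_metrics])),
        accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
        auc=auc,
        auc_ci=ci,
        pooled_sensitivity=pooled.sensitivity,
        pooled_specificity=pooled.specificity,
        pooled_accuracy=pooled.accuracy,
        confusion={
            "low_correct": pooled.tp_low,
            "low_missed": pooled.fn_low,
            "high_correct": pooled.tn_high,
            "high_missed": pooled.fp_high,
        },
        fold_metrics=fold_metrics,
        n_low=n_low,
        n_high=n_high,
        selected_features=list(used_features),
        selection_mode=("nested-" if nested_selection else "") + selection_mode,
        cv=config,
        warnings=all_warnings,
        pooled_scores=pooled_scores,
        pooled_labels=y,
    )
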