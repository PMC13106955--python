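"""Agreement and diagnostic metrics, cross-validation, and the
misalignment-perturbation experiment.

Agreement between predicted and reference trabecular parameters is measured
with the intraclass correlation coefficient in its two-way random-effects,
absolute-agreement, single-measures form, ICC(2,1):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

from the two-way ANOVA mean squares (rows = targets, columns = the two
raters).  Absolute agreement is the conservative choice for comparing a
method against a reference because it penalizes systematic offsets, not
just poor correlation.  The "overall" ICC of a report is the unweighted
mean of the four per-parameter ICCs.

Classification metrics (precision, recall, F1, rank-based AUC) and
stratified patient-level folds are delegated to scikit-learn; confidence
intervals come from a patient-level nonparametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .morphometry import PARAM_NAMES

__all__ = [
    "icc",
    "AgreementReport",
    "agreement_report",
    "roc_auc",
    "DiagnosticReport",
    "classification_report",
    "score_regression_report",
    "crossval",
    "perturbation_analysis",
    "paired_t_test",
]


def icc(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("icc needs two equal-length 1D vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("icc inputs must be finite")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total < 1e-300:
        raise ValueError("zero total variance: ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise ValueError("degenerate ANOVA decomposition: ICC undefined")
    return float((msr - mse) / denom)


@dataclass
class AgreementReport:
    per_parameter: dict[str, float]
    overall: float  # unweighted mean of the four per-parameter ICCs
    n_pairs: int
    icc_form: str = "ICC(2,1) absolute agreement"
    scatter: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def agreement_report(pred: np.ndarray, truth: np.ndarray,
                     keep_scatter: bool = False) -> AgreementReport:
    """Per-parameter ICC of (n, 4) predictions against references."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"expected matching (n, 4) arrays, got {pred.shape} / {truth.shape}")
    per = {name: icc(pred[:, j], truth[:, j]) for j, name in enumerate(PARAM_NAMES)}
    scatter = {name: (truth[:, j].copy(), pred[:, j].copy())
               for j, name in enumerate(PARAM_NAMES)} if keep_scatter else {}
    return AgreementReport(per, float(np.mean(list(per.values()))), len(pred),
                           scatter=scatter)


def roc_auc(labels, scores, n_boot: int = 2000, seed: int = 0
            ) -> tuple[float, tuple[float, float]]:
    """Rank-based (Mann-Whitney) AUC with a bootstrap 95% CI over subjects."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    auc = float(skm.roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(labels)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            continue
        boots.append(skm.roc_auc_score(labels[idx], scores[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return auc, (float(lo), float(hi))


@dataclass
class DiagnosticReport:
    precision: float
    recall: float
    f1: float
    auc: float
    auc_ci95: tuple[float, float]
    confusion: np.ndarray
    undefined_classes: list[int] = field(default_factory=list)


def classification_report(labels, predictions, scores=None, positive_label: int = 1,
                          seed: int = 0) -> DiagnosticReport:
    """Binary diagnostic metrics (disease vs normal).

    ``labels``/``predictions`` are 0/1; ``scores`` (probability of the
    positive class) feeds the AUC.  Precision for a class never predicted is
    reported as nan and flagged, not silently zeroed.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    cm = skm.confusion_matrix(labels, predictions, labels=[0, 1])
    undefined = [c for c in (0, 1) if predictions.tolist().count(c) == 0]
    prec = (skm.precision_score(labels, predictions, pos_label=positive_label,
                                zero_division=np.nan)
            if positive_label not in undefined else float("nan"))
    rec = skm.recall_score(labels, predictions, pos_label=positive_label, zero_division=0)
    f1 = (2 * prec * rec / (prec + rec)) if np.isfinite(prec) and (prec + rec) > 0 else (
        0.0 if np.isfinite(prec) else float("nan"))
    if scores is not None and len(np.unique(labels)) == 2:
        auc, ci = roc_auc(labels, scores, seed=seed)
    else:
        auc, ci = float("nan"), (float("nan"), float("nan"))
    return DiagnosticReport(float(prec), float(rec), float(f1), auc, ci, cm, undefined)


def score_regression_report(truth, pred) -> dict[str, float]:
    """MAE and R^2 for the continuous severity-score task."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    mae = float(np.mean(np.abs(truth - pred)))
    ss_res = float(np.sum((truth - pred) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"mae": mae, "r2": r2}


def crossval(subject_ids, class_labels, k_folds: int = 5, seed: int = 0
             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified patient-level folds: every subject in exactly one test fold.

    Returns (train_ids, test_ids) per fold as arrays of subject identifiers.
    Raises when a fold would contain a single class in training.
    """
    subject_ids = np.asarray(subject_ids)
    class_labels = np.asarray(class_labels)
    if len(np.unique(subject_ids)) != len(subject_ids):
        raise ValueError("subject_ids must be unique (one row per patient)")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(subject_ids, class_labels):
        if len(np.unique(class_labels[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        folds.append((subject_ids[tr], subject_ids[te]))
    return folds


def paired_t_test(metric_a, metric_b) -> tuple[float, float]:
    """Paired t-test over fold-level metrics; returns (t, p)."""
    t, p = stats.ttest_rel(np.asarray(metric_a, float), np.asarray(metric_b, float))
    return float(t), float(p)


def perturbation_analysis(predict_fn, truth_fn, centers: np.ndarray,
                          offsets_mm=(0, 1, 2, 5, 10, 15), seed: int = 0
                          ) -> pd.DataFrame:
    """ICC of patch predictions against truths recomputed at displaced
    MR sampling coordinates.

    ``predict_fn(centers)`` returns (n, 4) parameter predictions and
    ``truth_fn(centers)`` the morphometric references at those physical
    coordinates (rows of nan where a patch cannot be formed).  For each
    offset the reference coordinates are displaced along a random unit
    direction scaled to the offset, emulating residual registration error in
    the MR patch sampling; predictions are held fixed.  Returns a table of
    (offset_mm, per-parameter ICC, overall, n).
    """
    centers = np.asarray(centers, dtype=float)
    rng = np.random.default_rng(seed)
    pred = np.asarray(predict_fn(centers), dtype=float)
    rows = []
    for off in offsets_mm:
        if off == 0:
            shifted = centers
        else:
            d = rng.standard_normal(centers.shape)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            shifted = centers + off * d
        truth = np.asarray(truth_fn(shifted), dtype=float)
        ok = np.all(np.isfinite(truth), axis=1) & np.all(np.isfinite(pred), axis=1)
        per = {name: icc(pred[ok, j], truth[ok, j])
               for j, name in enumerate(PARAM_NAMES)}
        rows.append({"offset_mm": off, **per,
                     "overall": float(np.mean(list(per.values()))), "n": int(ok.sum())})
    return pd.DataFrame(rows)
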