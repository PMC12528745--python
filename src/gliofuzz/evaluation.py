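"""Confusion-matrix metrics, error metrics, ROC-AUC, and K-fold orchestration.

HGG is the positive class throughout.  Metrics with a zero denominator
surface as ``None`` (an explicit undefined marker) rather than silent
zeros.  The printed definitions of MAE and RMSE in some sources omit the
absolute value / square; the standard forms are implemented here:
MAE = mean |y - x|, RMSE = sqrt(mean (y - x)^2).

ROC-AUC is computed by a threshold sweep with trapezoidal integration and
cross-checked internally against the rank-sum (Mann-Whitney) form with
half-credit for ties; the two must agree to 1e-12 or the call fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "classification_metrics",
    "error_metrics",
    "roc_auc",
    "roc_curve_points",
    "kfold_crossval",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Derived metric set; undefined entries (zero denominators) are None."""

    acc: Optional[float]
    rec: Optional[float]
    spe: Optional[float]
    pre: Optional[float]
    f1: Optional[float]
    n: int
    mae: Optional[float] = None
    rmse: Optional[float] = None
    auc: Optional[float] = None
    dice: Optional[float] = None

    def to_dict(self) -> Dict[str, object]:
        return {
            "schema_version": SCHEMA_VERSION,
            "ACC": self.acc, "Rec": self.rec, "Spe": self.spe,
            "Pre": self.pre, "F1": self.f1, "MAE": self.mae,
            "RMSE": self.rmse, "AUC": self.auc, "Dice": self.dice,
            "n": self.n,
        }


def confusion(labels: np.ndarray, preds: np.ndarray) -> ConfusionMatrix:
    """Counts with HGG (label 1) as the positive class."""
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    if labels.shape != preds.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {preds.shape}")
    if labels.size < 1:
        raise ValueError("need at least one sample")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (preds == 1))),
        tn=int(np.sum((labels == 0) & (preds == 0))),
        fp=int(np.sum((labels == 0) & (preds == 1))),
        fn=int(np.sum((labels == 1) & (preds == 0))),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """ACC, recall (sensitivity), specificity, precision, F1 from counts."""
    acc = _ratio(cm.tp + cm.tn, cm.total)
    rec = _ratio(cm.tp, cm.tp + cm.fn)
    spe = _ratio(cm.tn, cm.tn + cm.fp)
    pre = _ratio(cm.tp, cm.tp + cm.fp)
    if pre is None or rec is None or (pre + rec) == 0:
        f1 = None
    else:
        f1 = 2 * pre * rec / (pre + rec)
    return MetricsReport(acc=acc, rec=rec, spe=spe, pre=pre, f1=f1, n=cm.total)


def error_metrics(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """(MAE, RMSE) of probability scores against binary truth."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1]")
    err = labels - scores
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray):
    """(FPR, TPR) arrays from a sweep over the unique score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append(float(np.sum(pred & (labels == 1))) / n_pos)
        fpr.append(float(np.sum(pred & (labels == 0))) / n_neg)
    return np.array(fpr), np.array(tpr)


def _auc_ranksum(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney with average ranks: ties get half credit
    ranks = rankdata(scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC, verified against the rank-sum equivalence."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    fpr, tpr = roc_curve_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    auc_rank = _auc_ranksum(scores, labels)
    if not math.isclose(auc, auc_rank, abs_tol=1e-12):  # pragma: no cover
        raise AssertionError(
            f"trapezoidal AUC {auc} disagrees with rank-sum AUC {auc_rank}"
        )
    return auc


def kfold_crossval(
    cohort,
    k: int,
    spec=None,
    cfg=None,
) -> Tuple[float, float, pd.DataFrame]:
    """Stratified K-fold over the whole cohort; full two-stage run per fold.

    Returns (mean accuracy, standard deviation, per-fold table).  ``cfg``
    is a :class:`gliofuzz.training.TrainConfig`; its seed also seeds the
    fold assignment.
    """
    from .fcnn3d import NetworkSpec
    from .training import TrainConfig, predict, stage1_optimize, stage2_train, TrainedModel, _audit
    from .fuzzy_weights import build_kernel_bank
    from .fcnn3d import forward_features_batch

    spec = spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    volumes = cohort.volumes()
    labels = cohort.labels()
    minority = int(min(np.sum(labels == 1), np.sum(labels == 0)))
    if k > minority:
        raise ValueError(
            f"K={k} exceeds the minority-class count ({minority}); "
            "stratified folds would be single-class"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        tr_vols = [volumes[i] for i in train_idx]
        tr_y = labels[train_idx]
        genes, relu, _ = stage1_optimize(tr_vols, tr_y, spec, cfg)
        bank = build_kernel_bank(genes, spec)
        head, scaler = stage2_train(forward_features_batch(tr_vols, bank, relu), tr_y, cfg)
        model = TrainedModel(
            genes=genes, relu=relu, spec=spec, head_type=cfg.head,
            head=head, scaler=scaler, audit=_audit(genes, relu, cfg.head),
        )
        preds, _ = predict(model, [volumes[i] for i in test_idx])
        acc = float(np.mean(preds == labels[test_idx]))
        rows.append({"fold": fold, "n_test": len(test_idx), "accuracy": acc})
    table = pd.DataFrame(rows)
    return float(table["accuracy"].mean()), float(table["accuracy"].std(ddof=0)), table
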