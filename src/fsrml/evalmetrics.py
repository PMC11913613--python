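"""Classification metrics in the PRE/SEN/SPE/ACC/F1/ROC-AUC/PR-AUC vocabulary.

Threshold metrics come from a single confusion matrix; ranking metrics use
the trapezoidal ROC area (equivalently the Mann-Whitney statistic with 0.5
tie credit) and the step-wise precision-recall area (no linear
interpolation, which would overestimate).  Cross-validated reports pool the
out-of-fold predictions into one confusion matrix rather than averaging
per-fold metrics: PR-AUC on small single folds is unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EvalReport",
    "confusion_metrics",
    "roc_pr_auc",
    "crossval_report",
    "evaluate_predictions",
    "report_table",
]

METRIC_COLUMNS = ["PRE", "SEN", "SPE", "ACC", "F1", "ROC_AUC", "PR_AUC"]


@dataclass
class EvalReport:
    PRE: float
    SEN: float
    SPE: float
    ACC: float
    F1: float
    ROC_AUC: Optional[float]
    PR_AUC: Optional[float]
    n_positive: int
    n_negative: int

    def as_dict(self) -> dict:
        return {
            "PRE": self.PRE, "SEN": self.SEN, "SPE": self.SPE,
            "ACC": self.ACC, "F1": self.F1,
            "ROC_AUC": self.ROC_AUC, "PR_AUC": self.PR_AUC,
            "n_positive": self.n_positive, "n_negative": self.n_negative,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    """Threshold metrics from confusion-matrix counts.

    Precision is 0 by convention when no positive call is made.  Requires at
    least one true positive-class and one true negative-class subject.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("all-zero confusion matrix")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("need at least one subject in each true class")
    pre = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * pre * sen / (pre + sen) if (pre + sen) > 0 else 0.0
    return EvalReport(PRE=pre, SEN=sen, SPE=spe, ACC=acc, F1=f1,
                      ROC_AUC=None, PR_AUC=None,
                      n_positive=tp + fn, n_negative=tn + fp)


def roc_pr_auc(scores, labels) -> tuple[float, float]:
    """(ROC-AUC, PR-AUC) for continuous scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report: threshold metrics at ``threshold`` plus both AUCs."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    rep = confusion_metrics(tp, fp, tn, fn)
    rep.ROC_AUC, rep.PR_AUC = roc_pr_auc(scores, labels)
    return rep


def _model_scores(model, X) -> np.ndarray:
    """Positive-class score: predicted probability, else decision function."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        # squash onto (0, 1) so the 0.5 threshold keeps its meaning
        return 1.0 / (1.0 + np.exp(-model.decision_function(X)))
    return model.predict(X).astype(float)


def crossval_report(cohort, mask, base_model: str, folds: int = 5,
                    seed: int = 0, threshold: float = 0.5) -> EvalReport:
    """Pooled out-of-fold report for one feature mask and base model.

    Fold assignment is stratified and depends only on (cohort, folds, seed);
    out-of-fold scores are pooled across folds into a single report.
    """
    from .wrapper import make_base_model, mask_columns

    X = mask_columns(cohort, mask)
    y = np.asarray(cohort.y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, va in skf.split(X, y):
        model = make_base_model(base_model, seed=seed)
        model.fit(X[tr], y[tr])
        scores[va] = _model_scores(model, X[va])
    return evaluate_predictions(y, scores, threshold=threshold)


def report_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Rows of model-name -> metrics, in the canonical column order."""
    rows = []
    for name, rep in reports.items():
        row = {"model": name}
        row.update({c: rep.as_dict()[c] for c in METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["model"] + METRIC_COLUMNS)
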