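"""Confusion-matrix metrics, chance-corrected agreement, and ROC/AUC.

Binary scores are the usual confusion-count ratios (accuracy, sensitivity,
specificity, precision, F1); multiclass agreement is Cohen's kappa
(p_o - p_e)/(1 - p_e) with the chance term p_e from the marginal products of
the confusion matrix, and the Jaccard score is macro-averaged per-class
intersection over union.  Metrics with a zero denominator are reported as
NaN (undefined) and excluded from averages rather than zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "confusion_matrix",
    "binary_metrics",
    "cohen_kappa",
    "jaccard_score",
    "roc_auc",
    "stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred, positive):
    """Tally TP/FP/TN/FN with ``positive`` as the patient class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def confusion_matrix(y_true, y_pred, classes=None):
    """(n_classes, n_classes) counts; rows are truth, columns prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    idx = {c: k for k, c in enumerate(classes)}
    M = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M, classes


def _safe_div(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def binary_metrics(counts):
    """ACC, SEN, SPE, precision, recall, F1 from confusion counts.

    recall is sensitivity by definition; undefined ratios come back NaN.
    """
    c = counts
    acc = _safe_div(c.tp + c.tn, c.total, "ACC")
    sen = _safe_div(c.tp, c.tp + c.fn, "SEN")
    spe = _safe_div(c.tn, c.tn + c.fp, "SPE")
    prec = _safe_div(c.tp, c.tp + c.fp, "precision")
    if np.isnan(prec) or np.isnan(sen) or (prec + sen) == 0:
        if not (np.isnan(prec) or np.isnan(sen)):
            warnings.warn("F1 undefined (precision+recall is zero); NaN",
                          RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sen / (prec + sen)
    return {"ACC": acc, "SEN": sen, "SPE": spe, "precision": prec,
            "recall": sen, "F1": f1}


def cohen_kappa(confusion):
    """Cohen's kappa from a confusion matrix (rows truth, cols prediction).

    p_o = trace/total, p_e = sum_k row_k * col_k / total^2,
    kappa = (p_o - p_e)/(1 - p_e).  When p_e = 1 the statistic is defined as
    1 for perfect agreement and NaN otherwise.
    """
    M = np.asarray(confusion, dtype=float)
    total = M.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(M) / total
    p_e = float((M.sum(axis=1) * M.sum(axis=0)).sum()) / total ** 2
    if np.isclose(p_e, 1.0):
        if np.isclose(p_o, 1.0):
            return 1.0
        warnings.warn("kappa undefined (p_e = 1, imperfect agreement); NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def jaccard_score(y_true, y_pred, average="macro", positive=None):
    """Per-class intersection-over-union of the label sets.

    For class c: |{i: true_i = c and pred_i = c}| / |{i: true_i = c or
    pred_i = c}|.  ``average="macro"`` averages over the classes present in
    the truth (classes absent from both vectors are skipped);
    ``average="binary"`` reports the ``positive`` class only.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")

    def _one(c):
        inter = np.sum((y_true == c) & (y_pred == c))
        union = np.sum((y_true == c) | (y_pred == c))
        return inter / union if union > 0 else None

    if average == "binary":
        if positive is None:
            raise ValueError("binary averaging needs the positive class")
        v = _one(positive)
        return float("nan") if v is None else float(v)
    vals = [v for v in (_one(c) for c in np.unique(y_true)) if v is not None]
    return float(np.mean(vals))


def roc_auc(y_true, scores, positive=None):
    """Trapezoidal area under the ROC curve from continuous scores.

    Thresholds sweep the distinct score values from high to low; tied scores
    step TPR and FPR simultaneously.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if positive is None:
        if classes.size != 2:
            raise ValueError("positive class required for non-binary labels")
        positive = classes[-1]
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    order = np.argsort(-scores, kind="mergesort")
    pos_sorted = pos[order].astype(float)
    s_sorted = scores[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(1.0 - pos_sorted)
    # keep only the last index of each tied score block
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def stratified_kfold(labels, k=10, seed=0):
    """Seeded stratified k-fold index lists (train, test) per fold.

    Every class must have at least k members so each fold's test set can be
    stratified.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts < k]
        raise ValueError(
            f"classes {list(small)} have fewer than k={k} members; "
            "stratified folding infeasible")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in
            skf.split(np.zeros(labels.size), labels)]
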