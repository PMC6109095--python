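"""Evaluation metrics, implemented in-house and oracle-tested.

Matthews correlation coefficient (binary and its multiclass
generalisation), ROC area via the Mann-Whitney rank statistic with half
credit for ties, information gain in bits with supervised MDL binning of
numeric features, and the Zero-R majority-class baseline (accuracy = the
majority prevalence, AUC 0.5, MCC 0 by construction).
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.stats import rankdata


class MetricError(ValueError):
    pass


# -- confusion counts and MCC -------------------------------------------------

def confusion_matrix(y_true, y_pred, classes=None) -> tuple[np.ndarray, list]:
    """K x K confusion matrix (rows = true class) and class order."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred) or not y_true:
        raise MetricError("label vectors must be equal-length and non-empty")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    index = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        matrix[index[t], index[p]] += 1
    return matrix, list(classes)


def binary_counts(y_true, y_pred, positive) -> dict[str, int]:
    """TP/FP/FN/TN counts for a designated positive class."""
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for t, p in zip(y_true, y_pred):
        if p == positive:
            counts["tp" if t == positive else "fp"] += 1
        else:
            counts["fn" if t == positive else "tn"] += 1
    return counts


def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Binary MCC; returns 0 when any denominator factor is 0 (convention)."""
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise MetricError("negative confusion counts")
    if tp + fp + fn + tn == 0:
        raise MetricError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc(y_true, y_pred) -> float:
    """MCC from label vectors; the K>2 case uses the generalised
    (correlation-of-confusion-matrix) form, which reduces to binary MCC."""
    matrix, _ = confusion_matrix(y_true, y_pred)
    s = matrix.sum()
    c = np.trace(matrix)
    t = matrix.sum(axis=1).astype(float)  # true class totals
    p = matrix.sum(axis=0).astype(float)  # predicted class totals
    num = c * s - float(t @ p)
    den = math.sqrt(s * s - float(p @ p)) * math.sqrt(s * s - float(t @ t))
    if den == 0:
        return 0.0
    return num / den


# -- ROC / AUC ----------------------------------------------------------------

def roc_auc(scores, y_true, positive=None) -> float:
    """Probability a positive outranks a negative, ties at half credit
    (the Mann-Whitney form of the ROC area)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if positive is None:
        classes = sorted(set(y_true.tolist()))
        if len(classes) != 2:
            raise MetricError(
                f"AUC needs both classes present, got {classes}")
        positive = classes[-1]
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: a class is absent from y_true")
    ranks = rankdata(scores)  # average ranks give ties half credit
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_curve(scores, y_true, positive) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, threshold-descending."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(y_true) == positive
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    # collapse runs of equal scores
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0, tps[distinct]] / max(pos.sum(), 1)
    fpr = np.r_[0, fps[distinct]] / max((~pos).sum(), 1)
    return np.column_stack([fpr, tpr])


def macro_ovr_auc(score_matrix, y_true, classes) -> float:
    """Macro-averaged one-vs-rest AUC for multiclass problems; classes
    absent from y_true are skipped."""
    scores = np.asarray(score_matrix, dtype=float)
    aucs = []
    for j, cls in enumerate(classes):
        binary = np.asarray([t == cls for t in y_true])
        if binary.all() or not binary.any():
            continue
        aucs.append(roc_auc(scores[:, j], binary, positive=True))
    if not aucs:
        raise MetricError("AUC undefined: fewer than two classes present")
    return float(np.mean(aucs))


# -- entropy and information gain ---------------------------------------------

def entropy(labels) -> float:
    """Shannon entropy of a label vector, in bits."""
    labels = list(labels)
    if not labels:
        return 0.0
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def _split_entropy(labels_left, labels_right) -> float:
    n = len(labels_left) + len(labels_right)
    return (len(labels_left) / n * entropy(labels_left)
            + len(labels_right) / n * entropy(labels_right))


def mdl_discretize(values, labels) -> list[float]:
    """Supervised binning of a numeric feature (Fayyad-Irani MDL criterion).

    Returns the sorted list of accepted cut points (possibly empty: the
    feature is then uninformative under MDL).
    """
    pairs = sorted((float(v), l) for v, l in zip(values, labels)
                   if not (isinstance(v, float) and math.isnan(v)))
    cuts: list[float] = []

    def recurse(segment):
        n = len(segment)
        if n < 2:
            return
        values_seg = [v for v, _ in segment]
        labels_seg = [l for _, l in segment]
        base = entropy(labels_seg)
        best = None
        for i in range(1, n):
            if values_seg[i] == values_seg[i - 1]:
                continue
            e = _split_entropy(labels_seg[:i], labels_seg[i:])
            if best is None or e < best[0]:
                best = (e, i)
        if best is None:
            return
        e, i = best
        gain = base - e
        k = len(set(labels_seg))
        k1 = len(set(labels_seg[:i]))
        k2 = len(set(labels_seg[i:]))
        delta = (math.log2(3 ** k - 2)
                 - (k * base - k1 * entropy(labels_seg[:i])
                    - k2 * entropy(labels_seg[i:])))
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        cuts.append((values_seg[i - 1] + values_seg[i]) / 2)
        recurse(segment[:i])
        recurse(segment[i:])

    recurse(pairs)
    return sorted(cuts)


def _bin_numeric(values, cuts) -> list:
    out = []
    for v in values:
        if isinstance(v, float) and math.isnan(v):
            out.append("missing")
        else:
            out.append(int(np.searchsorted(cuts, float(v), side="right")))
    return out


def information_gain(feature, labels, numeric: bool | None = None) -> float:
    """H(labels) - H(labels | feature), in bits; never negative.

    Numeric features are first discretised by supervised MDL binning (a
    feature yielding no accepted cut gets a single bin, hence gain 0).
    """
    feature = list(feature)
    labels = list(labels)
    if len(feature) != len(labels) or len(labels) < 2:
        raise MetricError("need >=2 aligned rows")
    if numeric is None:
        numeric = all(isinstance(v, (int, float, np.integer, np.floating))
                      for v in feature)
    if numeric:
        feature = _bin_numeric(feature, mdl_discretize(feature, labels))
    n = len(labels)
    base = entropy(labels)
    conditional = 0.0
    groups: dict = {}
    for f, l in zip(feature, labels):
        groups.setdefault(f, []).append(l)
    for group in groups.values():
        conditional += len(group) / n * entropy(group)
    return max(base - conditional, 0.0)


# -- Zero-R baseline ----------------------------------------------------------

class ZeroR:
    """Majority-class constant classifier.

    Ties between classes break to the lexicographically smallest label
    (documented, deterministic).  Scores are constant, so its ROC area is
    0.5 and its MCC is 0 on any test set.
    """

    def __init__(self):
        self.majority_ = None
        self.classes_ = None

    def fit(self, X, y):
        y = list(y)
        if not y:
            raise MetricError("Zero-R needs at least one training label")
        counts = Counter(y)
        top = max(counts.values())
        self.majority_ = min(c for c, n in counts.items() if n == top)
        self.classes_ = sorted(counts)
        return self

    def predict(self, X):
        return np.array([self.majority_] * len(X))

    def predict_proba(self, X):
        proba = np.zeros((len(X), len(self.classes_)))
        proba[:, self.classes_.index(self.majority_)] = 1.0
        return proba

    def accuracy(self, y) -> float:
        y = list(y)
        return sum(v == self.majority_ for v in y) / len(y)
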