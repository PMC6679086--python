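"""Chance-level statistics for per-subject classification accuracy.

Under random guessing, the number of correct predictions among a subject's
n test trials follows Binomial(n, 1/c) for c classes.  The significance
threshold is the smallest accuracy whose cumulative probability under that
distribution reaches 1 - alpha (the inverse-CDF, as computed by MATLAB's
``binoinv``), expressed in percent:

    threshold(alpha, n, c) = binoinv(1 - alpha, n, 1/c) * 100 / n

A subject is "well classified" when its observed accuracy strictly exceeds
its own threshold.  Group-level comparisons of accuracy distributions use
the Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass(frozen=True)
class ThresholdParams:
    n: int
    c: int
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.c < 2:
            raise ValueError("c must be >= 2")


def chance_threshold(n: int, c: int, alpha: float = 0.05) -> float:
    """Binomial chance-level accuracy threshold, in percent.

    Returns 100/n times the smallest integer k whose Binomial(n, 1/c) CDF is
    at least 1 - alpha (exact inverse CDF, no normal approximation).
    """
    p = ThresholdParams(n=n, c=c, alpha=alpha)
    k = stats.binom.ppf(1.0 - p.alpha, p.n, 1.0 / p.c)
    return 100.0 * float(k) / p.n


def select_well_classified(fold_results, alpha: float = 0.05, n_classes=None):
    """Per-subject thresholding: retained iff accuracy > own threshold.

    fold_results is an iterable of FoldResult (or anything with
    test_subject, n_test_trials, accuracy and probabilities attributes).
    Returns (retained subject ids, table) where the table has one row per
    subject with its n, threshold, accuracy and retained flag.  The boundary
    is strict: accuracy exactly equal to the threshold is excluded.
    """
    rows = []
    for r in fold_results:
        c = n_classes or r.probabilities.shape[1]
        thr = chance_threshold(r.n_test_trials, c, alpha)
        rows.append({
            "subject": r.test_subject, "group": r.group,
            "n": r.n_test_trials, "threshold": thr,
            "accuracy": r.accuracy, "retained": bool(r.accuracy > thr),
        })
    table = pd.DataFrame(rows)
    retained = table.loc[table.retained, "subject"].tolist()
    return retained, table


def kruskal_wallis(*groups):
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Accepts two or more samples of per-subject accuracies.  The degenerate
    all-identical case returns H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def confusion_stats(y_true, y_pred, labels=None, positive=None):
    """Confusion matrix with sensitivity/specificity for the binary case.

    The positive class (clinically, the patient group) defaults to
    labels[-1].  Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP).
    For more than two classes only the matrix is returned (rates are None).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    matrix = _sk_confusion(y_true, y_pred, labels=labels)
    out = {"labels": list(labels), "matrix": matrix,
           "sensitivity": None, "specificity": None}
    if len(labels) == 2:
        if positive is None:
            positive = labels[-1]
        pos = list(labels).index(positive)
        neg = 1 - pos
        tp, fn = matrix[pos, pos], matrix[pos, neg]
        tn, fp = matrix[neg, neg], matrix[neg, pos]
        out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    return out
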