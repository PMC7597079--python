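"""Diagnostic-performance statistics for ordinal steatosis grading.

Implements the evaluation arm of the entropy-imaging study design: binarize
the ordinal grade at a criterion (>= mild / moderate / severe), split subjects
4:1 into train and test, choose the entropy cutoff on the training ROC curve
by the closest-to-(0,1) rule, and report confusion-matrix metrics plus AUROC
with a DeLong 95% confidence interval on the test set.  The DeLong
placement-value machinery also provides the paired test for comparing two
correlated AUROCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split

GRADES = ("normal", "mild", "moderate", "severe")

__all__ = [
    "GRADES",
    "ROCResult",
    "MetricsTable",
    "binarize",
    "split_train_test",
    "roc_analysis",
    "optimal_cutoff",
    "classify",
    "performance",
    "delong_placements",
    "delong_variance",
    "delong_test",
    "evaluate_pipeline",
    "ROCThresholdClassifier",
]


def binarize(grades, criterion: str) -> np.ndarray:
    """Binary labels for one grading criterion: 1 iff grade >= criterion."""
    if criterion not in GRADES[1:]:
        raise ValueError(f"criterion must be one of {GRADES[1:]}, got {criterion!r}")
    rank = {g: i for i, g in enumerate(GRADES)}
    try:
        r = np.array([rank[g] for g in grades])
    except KeyError as e:
        raise ValueError(f"unknown grade {e.args[0]!r}") from None
    labels = (r >= rank[criterion]).astype(int)
    if labels.min() == labels.max():
        warnings.warn(
            f"degenerate task: criterion >={criterion} yields a single class",
            stacklevel=2,
        )
    return labels


def split_train_test(
    subject_table: pd.DataFrame,
    labels,
    ratio: float = 4.0,
    seed: int | None = 0,
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level stratified train/test split with train:test = ratio.

    Splitting happens at subject granularity, so all repeated scans of one
    subject land on the same side.  n=205 with ratio 4 gives 164 train / 41
    test subjects.
    """
    labels = np.asarray(labels)
    if len(subject_table) != labels.size:
        raise ValueError("labels must align with the subject table")
    test_size = 1.0 / (ratio + 1.0)
    pos = np.arange(len(subject_table))
    tr_pos, te_pos = train_test_split(
        pos,
        test_size=test_size,
        random_state=seed,
        stratify=labels if stratify else None,
        shuffle=True,
    )
    if stratify:
        for part, name in ((tr_pos, "train"), (te_pos, "test")):
            if np.unique(labels[part]).size < np.unique(labels).size:
                raise ValueError(f"{name} split lost a class; cohort too small")
    return subject_table.iloc[np.sort(tr_pos)], subject_table.iloc[np.sort(te_pos)]


@dataclass
class ROCResult:
    """ROC curve with AUROC, DeLong variance/CI and (optionally) a cutoff."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    delong_variance: float | None = None
    ci95: tuple[float, float] | None = None
    cutoff: float | None = None
    degenerate_ci: bool = False  # perfect separation -> zero-width CI


def roc_analysis(scores, labels, with_ci: bool = True) -> ROCResult:
    """ROC curve, trapezoidal AUROC and DeLong variance / Wald 95% CI.

    Thresholds sit at the distinct score values (ties grouped into one
    vertex), so the trapezoidal area equals the Mann-Whitney statistic
    (ties counted 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC analysis requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    result = ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auroc=auroc)
    if with_ci and (labels == 1).sum() >= 2 and (labels == 0).sum() >= 2:
        a, var, ci = delong_variance(scores, labels)
        result.delong_variance = var
        result.ci95 = ci
        result.degenerate_ci = var == 0.0
    return result


def optimal_cutoff(roc: ROCResult) -> float:
    """Score threshold whose ROC vertex is closest to the perfect corner (0, 1).

    Minimizes sqrt(fpr^2 + (1-tpr)^2) over the ROC vertices; ties are broken
    toward higher specificity (lower fpr), then toward the higher threshold.
    The returned cutoff follows the convention "positive iff score >= cutoff".
    """
    d2 = roc.fpr**2 + (1.0 - roc.tpr) ** 2
    order = np.lexsort((-roc.thresholds, roc.fpr, d2))
    best = order[0]
    cutoff = float(roc.thresholds[best])
    roc.cutoff = cutoff
    return cutoff


def classify(scores, cutoff: float) -> np.ndarray:
    """Binary predictions: positive iff score >= cutoff."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


@dataclass
class MetricsTable:
    """Confusion-matrix-derived performance metrics.

    Ratios with a zero denominator are reported as NaN (missing), not 0.
    With a single confusion matrix, recall and sensitivity coincide by
    definition; both fields are kept for report compatibility.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num, den):
            return num / den if den > 0 else float("nan")

        n = self.tp + self.fp + self.tn + self.fn
        self.accuracy = ratio(self.tp + self.tn, n)
        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.precision = ratio(self.tp, self.tp + self.fp)
        self.recall = self.sensitivity
        p, r = self.precision, self.recall
        self.f1 = 2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r) and (p + r) > 0 else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def performance(pred, labels) -> MetricsTable:
    """Confusion-matrix metrics of binary predictions against labels."""
    pred = np.asarray(pred, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must have the same length")
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return MetricsTable(tp=tp, fp=fp, tn=tn, fn=fn)


def delong_placements(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong placement values.

    Returns (auroc, V10, V01): V10[i] is the mean over negatives of
    psi(x_i, y) for positive i; V01[j] the mean over positives of psi(x, y_j);
    psi = 1 / 0.5 / 0 for > / = / <.  The AUROC is the grand mean of psi.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(scores, labels) -> tuple[float, float, tuple[float, float]]:
    """AUROC, its DeLong variance and the Wald 95% CI (clipped to [0, 1]).

    var = S10/n1 + S01/n0 with S the sample variances (ddof=1) of the
    placement values.  Perfect separation yields variance 0 and a point CI.
    """
    auroc, v10, v01 = delong_placements(scores, labels)
    if v10.size < 2 or v01.size < 2:
        raise ValueError("DeLong variance needs >= 2 subjects in each class")
    var = float(v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auroc - half), min(1.0, auroc + half))
    return auroc, var, ci


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test comparing two correlated AUROCs.

    Both score vectors must be over the same subjects and labels.  The
    covariance uses the joint placement vectors:
    cov = S10_ab/n1 + S01_ab/n0;  z = (A_a - A_b)/sqrt(var_a + var_b - 2 cov).
    Returns (z, two-sided p).  A zero-variance difference (identical or
    perfectly concordant classifiers) is flagged as z=0, p=1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired test requires aligned score and label vectors")
    auc_a, v10a, v01a = delong_placements(scores_a, labels)
    auc_b, v10b, v01b = delong_placements(scores_b, labels)
    n1, n0 = v10a.size, v01a.size
    if n1 < 2 or n0 < 2:
        raise ValueError("DeLong test needs >= 2 subjects in each class")
    var_a = v10a.var(ddof=1) / n1 + v01a.var(ddof=1) / n0
    var_b = v10b.var(ddof=1) / n1 + v01b.var(ddof=1) / n0
    cov = (
        np.cov(v10a, v10b, ddof=1)[0, 1] / n1
        + np.cov(v01a, v01b, ddof=1)[0, 1] / n0
    )
    denom2 = var_a + var_b - 2.0 * cov
    if denom2 <= 1e-15:
        warnings.warn("zero variance of the AUROC difference; test degenerate", stacklevel=2)
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(denom2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


class ROCThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold classifier fit by ROC analysis.

    ``fit`` computes the ROC curve of the (1-D) score against the binary
    label, the trapezoidal AUROC with DeLong variance and Wald 95% CI, and
    the cutoff minimizing the Euclidean distance of the ROC vertex to (0, 1).
    ``predict`` applies "positive iff score >= cutoff_".

    Attributes
    ----------
    roc_ : ROCResult
    cutoff_ : float
    auroc_ : float
    ci95_ : tuple of float
    classes_ : ndarray of shape (2,)
    """

    def __init__(self, with_ci: bool = True):
        self.with_ci = with_ci

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("ROCThresholdClassifier expects a single feature")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        scores = self._scores(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary labels required")
        self.roc_ = roc_analysis(scores, y, with_ci=self.with_ci)
        self.cutoff_ = optimal_cutoff(self.roc_)
        self.auroc_ = self.roc_.auroc
        self.ci95_ = self.roc_.ci95
        self.n_features_in_ = 1
        return self

    def decision_function(self, X):
        return self._scores(X) - self.cutoff_

    def predict(self, X):
        return classify(self._scores(X), self.cutoff_)


def evaluate_pipeline(
    subject_table: pd.DataFrame,
    criteria=("mild", "moderate", "severe"),
    ratio: float = 4.0,
    seed: int | None = 0,
    score_column: str = "entropy_mean",
    grade_column: str = "grade",
) -> pd.DataFrame:
    """Full diagnostic evaluation over a set of grading criteria.

    For each criterion: binarize the grades, split subjects train:test =
    ratio, fit the ROC cutoff on the training subjects, and report the test
    confusion-matrix metrics plus the test AUROC with its DeLong 95% CI.
    Returns one row per criterion (cutoff, accuracy, sensitivity,
    specificity, precision, recall, F1, AUROC, CI bounds, split sizes).
    """
    rows = []
    table = subject_table.reset_index(drop=True)
    for criterion in criteria:
        labels = binarize(table[grade_column], criterion)
        tr, te = split_train_test(table, labels, ratio=ratio, seed=seed)
        y_tr = labels[tr.index.to_numpy()]
        y_te = labels[te.index.to_numpy()]
        clf = ROCThresholdClassifier().fit(tr[score_column].to_numpy(), y_tr)
        pred = clf.predict(te[score_column].to_numpy())
        m = performance(pred, y_te)
        test_roc = roc_analysis(te[score_column].to_numpy(), y_te)
        rows.append(
            {
                "criterion": f">={criterion}",
                "cutoff": clf.cutoff_,
                **m.as_dict(),
                "auroc": test_roc.auroc,
                "ci95_low": test_roc.ci95[0] if test_roc.ci95 else float("nan"),
                "ci95_high": test_roc.ci95[1] if test_roc.ci95 else float("nan"),
                "n_train": len(tr),
                "n_test": len(te),
            }
        )
    return pd.DataFrame(rows)
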