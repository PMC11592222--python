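"""ROC AUC with DeLong variance and the paired DeLong test.

The AUC is the Mann-Whitney two-sample statistic: the proportion of
(positive, negative) score pairs ranked concordantly, ties counting 1/2.
Its sampling variance, and the covariance between the AUCs of two scores
measured on the same individuals, come from DeLong's placement values
("structural components"): for each positive, the fraction of negatives it
outranks, and vice versa. This supports comparing the discrimination of
nested logistic risk models fitted to the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .risk_models import LogisticFit, fit_logistic

__all__ = ["ROCResult", "DeLongComparison", "roc_auc", "delong_paired",
           "compare_nested_models", "roc_points"]


@dataclass(frozen=True)
class ROCResult:
    """AUC with its DeLong variance and class sizes."""

    auc: float
    n_pos: int
    n_neg: int
    variance: float


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two AUCs on the same individuals."""

    auc_1: float
    auc_2: float
    z: float
    p_value: float


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative).

    V10_i = fraction of negatives scored below positive i (ties 1/2);
    V01_j = fraction of positives scored above negative j (ties 1/2).
    Midrank-based, O(n log n).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    return v10, v01


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Mann-Whitney AUC and DeLong variance of one score vector."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return ROCResult(auc=auc, n_pos=m, n_neg=n, variance=float(s10 / m + s01 / n))


def delong_paired(
    scores_1: np.ndarray, scores_2: np.ndarray, labels: np.ndarray
) -> DeLongComparison:
    """DeLong's test for the difference of two correlated AUCs.

    Both score vectors must be measured on the same individuals with the
    same labels. z = (auc_2 - auc_1) / sqrt(var_1 + var_2 - 2 cov); the
    p-value is two-sided normal. Raises when the variance of the AUC
    difference is zero (e.g. identical rankings).
    """
    scores_1 = np.asarray(scores_1, dtype=float)
    scores_2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores_1.shape != scores_2.shape or scores_1.shape != labels.shape:
        raise ValueError("paired scores and labels must have the same length")
    v10_1, v01_1 = _placements(scores_1, labels)
    v10_2, v01_2 = _placements(scores_2, labels)
    m, n = v10_1.size, v01_1.size
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())

    def cov(a, b, k):
        return float(((a - a.mean()) * (b - b.mean())).sum() / (k - 1)) if k > 1 else 0.0

    var1 = cov(v10_1, v10_1, m) / m + cov(v01_1, v01_1, n) / n
    var2 = cov(v10_2, v10_2, m) / m + cov(v01_2, v01_2, n) / n
    cov12 = cov(v10_1, v10_2, m) / m + cov(v01_1, v01_2, n) / n
    var_diff = var1 + var2 - 2 * cov12
    if var_diff <= 0:
        if auc1 == auc2:
            # Identical rankings: no evidence of a difference by construction.
            return DeLongComparison(auc_1=auc1, auc_2=auc2, z=0.0, p_value=1.0)
        raise ValueError("zero variance of the AUC difference")
    z = (auc2 - auc1) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongComparison(auc_1=auc1, auc_2=auc2, z=float(z), p_value=float(p))


def compare_nested_models(
    design_base: np.ndarray | pd.DataFrame,
    design_full: np.ndarray | pd.DataFrame,
    outcome: np.ndarray,
) -> tuple[DeLongComparison, LogisticFit, LogisticFit]:
    """Fit two logistic models and DeLong-compare their in-sample ROC AUCs.

    Scores are the fitted probabilities of each model on the same cohort
    (no cross-validation), mirroring the within-cohort comparison of a
    risk model with and without the polygenic score.
    """
    outcome = np.asarray(outcome, dtype=float)
    fit_base = fit_logistic(design_base, outcome)
    fit_full = fit_logistic(design_full, outcome)
    cmp = delong_paired(
        fit_base.fitted_probabilities, fit_full.fitted_probabilities, outcome
    )
    return cmp, fit_base, fit_full


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (threshold, sensitivity, 1-specificity) for export."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last_of_value = np.r_[s[1:] != s[:-1], True]
    return pd.DataFrame(
        {
            "threshold": s[last_of_value],
            "sensitivity": tp[last_of_value] / n_pos,
            "one_minus_specificity": fp[last_of_value] / n_neg,
        }
    )
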