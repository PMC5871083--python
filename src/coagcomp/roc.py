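"""ROC curves, AUROC and paired AUROC comparison for activity biomarkers.

AUROC is computed by the tie-corrected Mann-Whitney formulation (ties
count one half); the curve is swept over all distinct score thresholds, so
its trapezoidal area equals the U-statistic value by construction.  Paired
AUROC differences are tested with DeLong's covariance-based z test.
Markers where a *lower* value signals activity (C4, C3) are entered with
``higher_is_risk=False``, which negates the scores before ranking;
flipping the flag maps AUROC to 1 - AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .biomarker import PredictiveEquation, predict_probability


@dataclass
class ROCResult:
    marker: str
    auroc: float
    fpr: np.ndarray  # 1 - specificity, non-decreasing from 0 to 1
    tpr: np.ndarray  # sensitivity, non-decreasing from 0 to 1
    n_pos: int
    n_neg: int


def _validate_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("labels are single-class; both outcomes required")
    return s, y


def auroc(scores, labels, *, higher_is_risk: bool = True, marker: str = "") -> ROCResult:
    """Tie-corrected Mann-Whitney AUROC plus the full ROC curve.

    All-tied scores yield AUROC 0.5 (with a warning) and the two-point
    chance diagonal.
    """
    s, y = _validate_scores_labels(scores, labels)
    if not higher_is_risk:
        s = -s
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if np.ptp(s) == 0:
        warnings.warn("all scores tied; AUROC is 0.5 by convention")
        area = 0.5
    else:
        ranks = stats.rankdata(s)  # midranks handle ties (count 1/2)
        u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
        area = float(u / (n_pos * n_neg))

    # curve: sweep distinct thresholds from high to low
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return ROCResult(marker, area, fpr, tpr, n_pos, n_neg)


def combined_score(
    code_d, code_c, eq: PredictiveEquation
):
    """Per-patient score of the two-marker combination: the model probability.

    Any strictly increasing transform of z gives the same ROC, so scoring
    by P or by z is equivalent.
    """
    return np.atleast_1d(np.asarray(predict_probability(eq, code_d, code_c)))


@dataclass
class DeLongComparison:
    auroc_a: float
    auroc_b: float
    difference: float
    z: float
    p: float


def _delong_placements(scores, y):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.r_[pos, neg])
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def compare_aurocs(scores_a, scores_b, labels) -> DeLongComparison:
    """DeLong paired z test for the AUROC difference of two markers
    measured on the same patients (scores already oriented so higher =
    more likely active)."""
    a, y = _validate_scores_labels(scores_a, labels)
    b, y2 = _validate_scores_labels(scores_b, labels)
    if a.size != b.size or (y != y2).any():
        raise ValueError("paired comparison requires identical patients/labels")
    v10_a, v01_a = _delong_placements(a, y)
    v10_b, v01_b = _delong_placements(b, y)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / m + s01[0, 0] / n
        + s10[1, 1] / m + s01[1, 1] / n
        - 2 * (s10[0, 1] / m + s01[0, 1] / n)
    )
    diff = auc_a - auc_b
    if var <= 0:
        # identical (or perfectly concordant) markers: no evidence of difference
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, diff, float(z), p)
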