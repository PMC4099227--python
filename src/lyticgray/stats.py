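"""Group-level statistics: descriptives, two-sample t-tests, and
nonparametric ROC/AUC.

The diagnostic-ability statistic is the tie-corrected Mann-Whitney
estimator of the area under the ROC curve,

    AUC = [ #(pos > neg) + 0.5 * #(pos == neg) ] / (n_pos * n_neg),

with the Hanley-McNeil standard error and a two-sided normal test of the
null AUC = 0.5 using the null-hypothesis variance.  The trapezoidal area
under the empirical ROC curve is algebraically identical to this
estimator.  For two normal score distributions the population AUC has the
binormal closed form Phi(dmu / sqrt(sd_pos^2 + sd_neg^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "DescriptiveStats",
    "TTestResult",
    "ROCResult",
    "descriptive_stats",
    "two_sample_t",
    "empirical_auc",
    "roc_curve_points",
    "binormal_auc",
    "delong_variance",
]


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    st_dev: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    p_value: float
    n_pos: int
    n_neg: int


def descriptive_stats(values) -> DescriptiveStats:
    """Mean, sample (n-1) standard deviation, min, max of a sequence.

    For n = 1 the standard deviation is 0 by convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return DescriptiveStats(mean=float(np.mean(v)), st_dev=sd,
                            min=float(np.min(v)), max=float(np.max(v)), n=int(v.size))


def two_sample_t(a, b, pooled: bool = True) -> TTestResult:
    """Two-sided independent two-sample t-test of equal means.

    pooled=True uses the equal-variance Student form (df = n_a + n_b - 2);
    pooled=False uses Welch's test with Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return TTestResult(t_stat=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def empirical_auc(pos, neg) -> ROCResult:
    """Tie-corrected Mann-Whitney AUC with Hanley-McNeil SE and null test.

    The p-value is the two-sided normal test of AUC = 0.5 evaluated with
    the Hanley-McNeil variance under the null (where Q1 = Q2 = 1/3).
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty group")
    # Midrank-based U counts ties as half, identical to explicit pair counting.
    u = float(sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic)
    n_pos, n_neg = pos.size, neg.size
    auc = u / (n_pos * n_neg)
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    var0 = (0.25 + (n_pos + n_neg - 2) * (1.0 / 3.0 - 0.25)) / (n_pos * n_neg)
    z = (auc - 0.5) / np.sqrt(var0)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return ROCResult(auc=float(auc), se=se, p_value=min(p, 1.0), n_pos=int(n_pos), n_neg=int(n_neg))


def delong_variance(pos, neg) -> float:
    """DeLong variance of the empirical AUC (optional alternative SE)."""
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs n >= 2 per group")
    # Structural components via placement values.
    cmp_mat = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)  # per-positive placements
    v01 = cmp_mat.mean(axis=0)  # per-negative placements
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def roc_curve_points(pos, neg) -> np.ndarray:
    """Empirical ROC curve as (fpr, tpr) rows, one per distinct threshold.

    Includes (0, 0) and (1, 1); both coordinates are non-decreasing, and
    the trapezoidal area over these points equals :func:`empirical_auc`.
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty group")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for independent normal score distributions:
    Phi((mu_pos - mu_neg) / sqrt(sd_pos**2 + sd_neg**2))."""
    if sd_pos < 0 or sd_neg < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = float(np.hypot(sd_pos, sd_neg))
    if denom == 0.0:
        raise ValueError("both standard deviations are zero")
    return float(sps.norm.cdf((mu_pos - mu_neg) / denom))
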