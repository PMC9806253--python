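"""Statistical kernel: AUC, DeLong comparison, Holm adjustment, Pearson
correlation and group comparisons (Welch/Student t, one-way ANOVA with
Tukey HSD).

The DeLong test compares the AUCs of two paired score vectors through the
covariance of their placement (structural) components; AUC itself uses the
Mann-Whitney formulation with half credit for ties.  Tests are two-sided
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form with 0.5 tie credit."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    ranks = sps.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class AucComparison:
    """Result of a paired DeLong comparison of two AUCs."""

    auc_a: float
    auc_b: float
    z: float
    p: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    tx = _midrank(np.concatenate([pos, neg]))
    tpos = _midrank(pos)
    tneg = _midrank(neg)
    theta = (tx[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tx[:m] - tpos) / n
    v01 = 1.0 - (tx[m:] - tneg) / m
    return theta, v10, v01


def delong_test(scores_a, scores_b, labels, paired: bool = True) -> AucComparison:
    """Two-sided DeLong test for the difference of two paired AUCs.

    Both score vectors must be evaluated on the same patients.  Degenerate
    placement variance (e.g. identical score vectors) yields z = 0, p = 1
    with a warning.
    """
    if not paired:
        raise NotImplementedError("only the paired comparison is implemented")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    th_a, v10_a, v01_a = _placements(a, y)
    th_b, v10_b, v01_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0 or not np.isfinite(var):
        warnings.warn("degenerate DeLong variance; returning p = 1")
        return AucComparison(float(th_a), float(th_b), 0.0, 1.0)
    z = (th_a - th_b) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return AucComparison(float(th_a), float(th_b), float(z), float(p))


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving, monotone, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-distributed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupComparison:
    """Two-group t-test or one-way ANOVA (+ Tukey HSD) result."""

    test: str
    statistic: float
    p: float
    tukey: list[dict] = field(default_factory=list)


def group_compare(values, groups, equal_var: bool = False) -> GroupComparison:
    """Compare a continuous variable across groups.

    Two groups: t-test (Welch by default; ``equal_var=True`` for the
    classical pooled-variance Student test).  Three or more: one-way ANOVA
    with post-hoc Tukey HSD pairwise comparisons.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keys = [k for k in dict.fromkeys(groups.tolist())]
    samples = [values[groups == k] for k in keys]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    if len(samples) == 2:
        t, p = sps.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        return GroupComparison(name, float(t), float(p))
    f, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    table = [
        {
            "group_a": str(keys[i]),
            "group_b": str(keys[j]),
            "difference": float(np.mean(samples[i]) - np.mean(samples[j])),
            "p": float(hsd.pvalue[i, j]),
        }
        for i in range(len(keys))
        for j in range(i + 1, len(keys))
    ]
    return GroupComparison("anova", float(f), float(p), table)
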