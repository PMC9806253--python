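"""Feature stability filtering and univariate AUC ranking.

Radiomic features that are not robust to re-segmentation are removed
first: each feature's ICC(2,1) — single-rater absolute agreement from a
two-way random-effects ANOVA — is computed over a subset of patients
segmented twice (by design 20 of them), and features with ICC below 0.8
are dropped.  The surviving features are then ranked by their univariate
discriminative AUC on the training cohort and the top 50 are kept (all of
them when fewer than 50 are stable).

Both steps are exposed as sklearn-style transformers (`StabilityFilter`,
`TopAucSelector`) operating on pandas DataFrames (rows = patients,
columns = features), plus thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin


def _icc21_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) for paired rating columns.

    ``a``, ``b``: (n_subjects, n_features) ratings by two raters.  Uses the
    two-way random-effects ANOVA decomposition:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with k = 2.
    Features with no between-subject variance return 0 (agreement
    undefined).
    """
    n = a.shape[0]
    k = 2
    x = np.stack([a, b], axis=1).astype(float)  # (n, 2, F)
    grand = x.mean(axis=(0, 1))
    row_mean = x.mean(axis=1)  # (n, F)
    col_mean = x.mean(axis=0)  # (2, F)
    ssr = k * ((row_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((col_mean - grand) ** 2).sum(axis=0)
    sst = ((x - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    bad = (ssr <= 1e-12 * np.maximum(sst, 1e-30)) | ~np.isfinite(icc)
    if np.any(bad):
        icc = np.where(bad, 0.0, icc)
    return icc


def icc_2way_random(ratings) -> float:
    """ICC(2,1), single-rater absolute agreement, for an (n_subjects, 2) table."""
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) array")
    if r.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    icc = _icc21_columns(r[:, :1], r[:, 1:])
    val = float(icc[0])
    if val == 0.0 and np.var(r.mean(axis=1)) <= 1e-12 * max(np.var(r), 1e-30):
        warnings.warn("zero between-subject variance: ICC undefined, returning 0")
    return val


def auc_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Mann-Whitney AUC (0.5 tie credit) of features against a
    binary label."""
    y = np.asarray(y).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    ranks = rankdata(X, axis=0)
    return (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


@dataclass
class StabilityResult:
    """Per-feature re-segmentation stability verdict."""

    feature: str
    icc: float
    stable: bool


class StabilityFilter(TransformerMixin, BaseEstimator):
    """Drop features whose re-segmentation ICC(2,1) falls below a threshold.

    Parameters
    ----------
    threshold : float, default 0.8
        Minimum ICC for a feature to be considered stable.
    """

    def __init__(self, threshold: float = 0.8):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, X_repeat: pd.DataFrame):
        """Fit from paired original/repeat feature tables.

        Rows of ``X`` and ``X_repeat`` must be the same patients in the
        same order (the re-segmented subset); columns are features.
        """
        missing = [c for c in X.columns if c not in X_repeat.columns]
        if missing:
            raise ValueError(f"repeat table is missing features: {missing[:5]}...")
        Xr = X_repeat[X.columns]
        if len(X) != len(Xr):
            raise ValueError("original and repeat tables must pair the same patients")
        icc = _icc21_columns(X.to_numpy(float), Xr.to_numpy(float))
        self.feature_names_in_ = np.asarray(X.columns)
        self.icc_ = pd.Series(icc, index=X.columns)
        self.stable_mask_ = icc >= self.threshold
        self.stable_features_ = list(X.columns[self.stable_mask_])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.stable_features_]

    def results(self) -> list[StabilityResult]:
        return [
            StabilityResult(f, float(i), bool(s))
            for f, i, s in zip(self.icc_.index, self.icc_, self.stable_mask_)
        ]


class TopAucSelector(TransformerMixin, BaseEstimator):
    """Keep the k features with the highest univariate discriminative AUC.

    Parameters
    ----------
    k : int, default 50
        Number of features to keep; all features are kept when fewer than
        ``k`` are offered.
    direction_agnostic : bool, default True
        Rank by max(AUC, 1-AUC), treating features anti-correlated with
        the endpoint as equally informative.  Set False for the literal
        "highest AUC" ranking.

    Ties are broken lexicographically on the feature name so the selection
    is deterministic.
    """

    def __init__(self, k: int = 50, direction_agnostic: bool = True):
        self.k = k
        self.direction_agnostic = direction_agnostic

    def fit(self, X: pd.DataFrame, y):
        auc = auc_columns(X.to_numpy(float), np.asarray(y))
        self.auc_ = pd.Series(auc, index=X.columns)
        score = np.maximum(auc, 1 - auc) if self.direction_agnostic else auc
        order = sorted(
            range(len(score)), key=lambda j: (-score[j], str(X.columns[j]))
        )
        n_sel = min(self.k, len(order))
        self.ranking_ = [X.columns[j] for j in order]
        self.selected_features_ = self.ranking_[:n_sel]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]


def filter_stable(
    features: pd.DataFrame, resegmented: pd.DataFrame, threshold: float = 0.8
) -> list[StabilityResult]:
    """Per-feature ICC over the re-segmented pairs; features below the
    threshold are flagged unstable."""
    ids = resegmented.index
    f = StabilityFilter(threshold).fit(features.loc[ids], resegmented)
    return f.results()


def rank_by_auc(
    stable_features: pd.DataFrame,
    labels,
    top_k: int = 50,
    direction_agnostic: bool = True,
) -> TopAucSelector:
    """Rank stable features by training-cohort AUC and keep the top k."""
    return TopAucSelector(top_k, direction_agnostic).fit(stable_features, labels)
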