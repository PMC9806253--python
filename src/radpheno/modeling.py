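"""LASSO radiomic score models, model fusion and the three-class caller.

Two binary endpoints are modeled: *inflamed vs non-inflamed* from
whole-tumor features, and *immune-desert vs immune-excluded* from
peripheral-rim features.  For each endpoint an L1-penalized logistic
regression (LASSO; glmnet-style, alpha = 1) is fit per DCE phase on the
top-ranked features of that phase's RFG, with the penalty chosen at the
minimum mean 5-fold cross-validated deviance.  The radiomic score is the
linear predictor over standardized features.

Two fusion strategies combine the four phase models: the score-combined
model (SC) refits a LASSO on the four phase scores, and the
feature-combined model (FC) refits a LASSO on the union of features the
phase models selected.  Optimal cutoffs maximize Youden's index
(sensitivity + specificity) on training scores; cascading the whole-tumor
cutoff then the peripheral cutoff yields the three-class immunophenotype
call: high whole score -> inflamed, otherwise high peripheral score ->
excluded, else desert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

CLASSES = ("desert", "excluded", "inflamed")


# ---------------------------------------------------------------------------
# cohort splitting


@dataclass
class CohortSplit:
    """A reproducible training/validation partition of patient ids."""

    training: list
    validation: list
    seed: int

    def __post_init__(self):
        if set(self.training) & set(self.validation):
            raise ValueError("training and validation sets overlap")


def _largest_remainder(counts: np.ndarray, frac: float, total: int) -> np.ndarray:
    """Allocate ``total`` training slots over classes, closest to ``frac`` each."""
    quota = counts * frac
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = total - base.sum()
    order = np.argsort(-rem, kind="stable")
    alloc = base.copy()
    for j in order[:short]:
        alloc[j] += 1
    return np.minimum(alloc, counts)


def split_cohort(ids, seed: int, ratio=(3, 1), stratify=None) -> CohortSplit:
    """Random 3:1 training/validation split, optionally stratified.

    The training size is ``ceil(frac * n)`` (182 patients -> 137/45); with
    stratification every class is within one patient of the global ratio.
    """
    ids = list(ids)
    n = len(ids)
    if n < sum(ratio) * 2:
        raise ValueError(f"cohort of {n} too small for a {ratio[0]}:{ratio[1]} split")
    frac = ratio[0] / (ratio[0] + ratio[1])
    n_train = int(np.ceil(frac * n))
    rng = np.random.default_rng(seed)
    if stratify is None:
        perm = rng.permutation(n)
        train = [ids[i] for i in perm[:n_train]]
        val = [ids[i] for i in perm[n_train:]]
    else:
        stratify = np.asarray(stratify)
        if stratify.shape[0] != n:
            raise ValueError("stratify labels must align with ids")
        classes = sorted(set(stratify.tolist()))
        counts = np.array([(stratify == c).sum() for c in classes])
        alloc = _largest_remainder(counts, frac, n_train)
        train, val = [], []
        for c, k in zip(classes, alloc):
            members = [i for i, s in zip(ids, stratify) if s == c]
            perm = rng.permutation(len(members))
            train += [members[i] for i in perm[:k]]
            val += [members[i] for i in perm[k:]]
    return CohortSplit(train, val, seed)


# ---------------------------------------------------------------------------
# LASSO score model


class LassoScoreModel(BaseEstimator):
    """L1-penalized logistic radiomic score model with CV-selected penalty.

    Features are standardized to zero mean / unit variance on the training
    data before penalization; the reported score is the linear predictor
    ``beta_0 + sum_j beta_j x~_j`` over standardized selected features,
    reproducible from the stored parameters alone.

    Parameters
    ----------
    cv : int, default 5
        Stratified cross-validation folds for the penalty path.
    Cs : int or array, default 16
        Inverse-penalty grid passed to sklearn (log-spaced over C in
        [1e-3, 10]; weaker penalties are never CV-optimal here and only
        slow the solver); the glmnet-scale penalty is reported as
        ``lambda_ = 1 / (C * n_train)``.
    max_iter : int, default 10_000
        Solver iteration cap.
    tol : float, default 2e-3
        Solver convergence tolerance (selection is insensitive well below
        this level).
    random_state : int, default 0
        Fold shuffling seed.
    on_null : {"warn", "raise"}, default "warn"
        Behaviour when the CV-optimal penalty shrinks every coefficient to
        zero: degrade to an intercept-only (constant-score) model with a
        warning, or raise.
    """

    def __init__(
        self,
        cv: int = 5,
        Cs=16,
        max_iter: int = 10_000,
        tol: float = 2e-3,
        random_state: int = 0,
        on_null: str = "warn",
    ):
        self.cv = cv
        self.Cs = Cs
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.on_null = on_null

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) != 2:
            raise ValueError("y must contain both classes")
        X = pd.DataFrame(X)
        self.feature_names_in_ = [str(c) for c in X.columns]
        A = X.to_numpy(float)
        self.mean_ = A.mean(axis=0)
        sd = A.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (A - self.mean_) / self.scale_
        cs = (
            np.logspace(-3, 1, self.Cs) if np.isscalar(self.Cs) else np.asarray(self.Cs)
        )
        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        clf = LogisticRegressionCV(
            Cs=cs,
            cv=folds,
            penalty="l1",
            solver="saga",
            scoring="neg_log_loss",
            max_iter=self.max_iter,
            tol=self.tol,
            n_jobs=1,
            refit=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Z, y)
        self.coef_ = clf.coef_.ravel().copy()
        self.intercept_ = float(clf.intercept_[0])
        self.C_ = float(clf.C_[0])
        self.lambda_ = 1.0 / (self.C_ * len(y))
        nz = np.flatnonzero(np.abs(self.coef_) > 1e-12)
        self.coef_[np.abs(self.coef_) <= 1e-12] = 0.0
        self.selected_features_ = [self.feature_names_in_[j] for j in nz]
        self.degenerate_ = len(nz) == 0
        if self.degenerate_:
            if self.on_null == "raise":
                raise RuntimeError(
                    "degenerate LASSO path: all coefficients are zero at the "
                    "CV-optimal penalty"
                )
            warnings.warn(
                "LASSO selected the null model at the CV-optimal penalty; "
                "scores are constant (intercept only)"
            )
        self.cutoff_ = None
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Radiomic score from the stored standardization and coefficients."""
        X = pd.DataFrame(X)[self.feature_names_in_]
        Z = (X.to_numpy(float) - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cut = self.cutoff_ if self.cutoff_ is not None else 0.0
        return (self.decision_function(X) >= cut).astype(int)

    def to_dict(self) -> dict:
        return {
            "kind": "lasso",
            "features": self.feature_names_in_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "C": self.C_,
            "lambda": self.lambda_,
            "cutoff": self.cutoff_,
            "selected": self.selected_features_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LassoScoreModel":
        m = cls()
        m.feature_names_in_ = list(d["features"])
        m.mean_ = np.asarray(d["mean"], dtype=float)
        m.scale_ = np.asarray(d["scale"], dtype=float)
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.intercept_ = float(d["intercept"])
        m.C_ = float(d["C"])
        m.lambda_ = float(d["lambda"])
        m.cutoff_ = d.get("cutoff")
        m.selected_features_ = list(d["selected"])
        m.degenerate_ = len(m.selected_features_) == 0
        return m


def fit_lasso_rm(X: pd.DataFrame, y, **kwargs) -> LassoScoreModel:
    """Fit a single-RFG radiomic score model (thin wrapper)."""
    return LassoScoreModel(**kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# fusion models


class ScoreCombinedModel(BaseEstimator):
    """Score-combined (SC) fusion: LASSO over the four per-phase scores.

    Stores the nested phase models so held-out patients can be scored
    end-to-end from their four RFG tables.
    """

    def __init__(self, phase_models: dict, **lasso_kwargs):
        if len(phase_models) < 2:
            raise ValueError("need at least 2 phase models to combine")
        self.phase_models = dict(phase_models)
        self.lasso_kwargs = lasso_kwargs

    def _score_table(self, tables: dict) -> pd.DataFrame:
        cols = {}
        index = None
        for k, m in self.phase_models.items():
            t = tables[k]
            index = t.index if index is None else index
            cols[f"score_{k}"] = m.decision_function(t.loc[index])
        return pd.DataFrame(cols, index=index)

    def fit(self, tables: dict, y):
        self.model_ = LassoScoreModel(**self.lasso_kwargs).fit(
            self._score_table(tables), y
        )
        self.cutoff_ = None
        return self

    def decision_function(self, tables: dict) -> np.ndarray:
        return self.model_.decision_function(self._score_table(tables))

    @property
    def selected_features_(self):
        return self.model_.selected_features_

    @property
    def degenerate_(self):
        return self.model_.degenerate_

    def to_dict(self) -> dict:
        return {
            "kind": "score_combined",
            "phases": {str(k): m.to_dict() for k, m in self.phase_models.items()},
            "model": self.model_.to_dict(),
            "cutoff": self.cutoff_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreCombinedModel":
        phases = {int(k): LassoScoreModel.from_dict(v) for k, v in d["phases"].items()}
        obj = cls(phases)
        obj.model_ = LassoScoreModel.from_dict(d["model"])
        obj.cutoff_ = d.get("cutoff")
        return obj


class FeatureCombinedModel(BaseEstimator):
    """Feature-combined (FC) fusion: LASSO refit on the pooled union of the
    features selected by the four phase models (phase-tagged names)."""

    def __init__(self, phase_models: dict, **lasso_kwargs):
        self.phase_models = dict(phase_models)
        self.lasso_kwargs = lasso_kwargs
        self.pooled_features = sorted(
            {
                (k, f)
                for k, m in self.phase_models.items()
                for f in m.selected_features_
            }
        )

    def _pooled_table(self, tables: dict) -> pd.DataFrame:
        index = tables[next(iter(self.phase_models))].index
        data = {
            f"p{k}:{f}": tables[k].loc[index, f].to_numpy(float)
            for k, f in self.pooled_features
        }
        return pd.DataFrame(data, index=index)

    def fit(self, tables: dict, y):
        if not self.pooled_features:
            # every phase model is intercept-only (expected on null data)
            if self.lasso_kwargs.get("on_null", "warn") == "raise":
                raise ValueError(
                    "empty feature union: no phase model selected any feature"
                )
            warnings.warn(
                "empty feature union: no phase model selected any feature; "
                "the feature-combined model is intercept-only"
            )
            self.model_ = None
            self.cutoff_ = None
            return self
        self.model_ = LassoScoreModel(**self.lasso_kwargs).fit(
            self._pooled_table(tables), y
        )
        self.cutoff_ = None
        return self

    def decision_function(self, tables: dict) -> np.ndarray:
        index = tables[next(iter(self.phase_models))].index
        if self.model_ is None:
            return np.zeros(len(index))
        return self.model_.decision_function(self._pooled_table(tables))

    @property
    def selected_features_(self):
        return [] if self.model_ is None else self.model_.selected_features_

    @property
    def degenerate_(self):
        return self.model_ is None or self.model_.degenerate_

    def to_dict(self) -> dict:
        return {
            "kind": "feature_combined",
            "pooled": [[int(k), f] for k, f in self.pooled_features],
            "phases": {str(k): m.to_dict() for k, m in self.phase_models.items()},
            "model": None if self.model_ is None else self.model_.to_dict(),
            "cutoff": self.cutoff_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureCombinedModel":
        phases = {int(k): LassoScoreModel.from_dict(v) for k, v in d["phases"].items()}
        obj = cls(phases)
        obj.pooled_features = [(int(k), f) for k, f in d["pooled"]]
        obj.model_ = (
            None if d["model"] is None else LassoScoreModel.from_dict(d["model"])
        )
        obj.cutoff_ = d.get("cutoff")
        return obj


def combine_scores_sc(phase_models: dict, tables: dict, y, **kw) -> ScoreCombinedModel:
    """Fit the score-combined fusion model on training data."""
    return ScoreCombinedModel(phase_models, **kw).fit(tables, y)


def combine_features_fc(
    phase_models: dict, tables: dict, y, **kw
) -> FeatureCombinedModel:
    """Fit the feature-combined fusion model on training data."""
    return FeatureCombinedModel(phase_models, **kw).fit(tables, y)


# ---------------------------------------------------------------------------
# cutoffs and the three-class caller


def optimal_cutoff(scores, labels) -> float:
    """Youden-optimal threshold: maximize sensitivity + specificity.

    Candidates are the midpoints of consecutive sorted unique scores
    (prediction rule: score >= cutoff -> positive); among ties the lowest
    cutoff is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    uniq = np.unique(s)
    if uniq.size == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2
    npos = y.sum()
    nneg = y.size - npos
    best_c, best_j = None, -np.inf
    for c in cands:
        pred = s >= c
        sens = (pred & y).sum() / npos
        spec = (~pred & ~y).sum() / nneg
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


@dataclass
class PhenotypeCall:
    """A single patient's cascaded three-class immunophenotype call."""

    whole_score: float
    peri_score: float
    call: str
    c_whole: float
    c_peri: float


def call_phenotype(whole_score, peri_score, c_whole: float, c_peri: float):
    """Two-stage three-class caller.

    Whole-tumor score at or above its cutoff -> inflamed (the whole score
    is oriented toward inflamed via its positive association with central
    CD8 density); otherwise the peripheral score decides excluded (high,
    consistent with peripheral CD8 density) versus desert (low).
    Scalar inputs return a :class:`PhenotypeCall`; array inputs an array of
    labels.
    """
    w = np.asarray(whole_score, dtype=float)
    p = np.asarray(peri_score, dtype=float)
    calls = np.where(w >= c_whole, "inflamed", np.where(p >= c_peri, "excluded", "desert"))
    if np.isscalar(whole_score) or w.ndim == 0:
        return PhenotypeCall(float(w), float(p), str(calls), c_whole, c_peri)
    return calls


class PhenotypeCaller(BaseEstimator):
    """Sklearn-style wrapper around the two fused models and their cutoffs.

    ``fit`` derives both Youden cutoffs from training tables; ``predict``
    emits three-class calls for new patients' whole/peri RFG tables.
    """

    def __init__(self, whole_model, peri_model):
        self.whole_model = whole_model
        self.peri_model = peri_model

    def fit(self, whole_tables: dict, peri_tables: dict, phenotypes):
        ph = np.asarray(phenotypes)
        w = self.whole_model.decision_function(whole_tables)
        self.c_whole_ = optimal_cutoff(w, ph == "inflamed")
        noninfl = ph != "inflamed"
        p = self.peri_model.decision_function(
            {k: t.loc[noninfl] for k, t in peri_tables.items()}
        )
        self.c_peri_ = optimal_cutoff(p, ph[noninfl] == "excluded")
        return self

    def predict(self, whole_tables: dict, peri_tables: dict) -> np.ndarray:
        w = self.whole_model.decision_function(whole_tables)
        p = self.peri_model.decision_function(peri_tables)
        return call_phenotype(w, p, self.c_whole_, self.c_peri_)


def evaluate(calls, truth) -> dict:
    """Three-class confusion matrix, accuracy, per-class and macro F1."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape or calls.size == 0:
        raise ValueError("calls and truth must be non-empty and aligned")
    labels = list(CLASSES)
    cm = confusion_matrix(truth, calls, labels=labels)
    per_class = f1_score(truth, calls, labels=labels, average=None, zero_division=0)
    return {
        "labels": labels,
        "confusion": pd.DataFrame(cm, index=labels, columns=labels),
        "accuracy": float(accuracy_score(truth, calls)),
        "f1_per_class": {c: float(f) for c, f in zip(labels, per_class)},
        "macro_f1": float(
            f1_score(truth, calls, labels=labels, average="macro", zero_division=0)
        ),
    }
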