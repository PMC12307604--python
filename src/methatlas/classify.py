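"""Subtype and 5-year-mortality classifiers on embedding coordinates.

Both classifiers are gradient-boosted decision-tree (LightGBM) models taking
the five embedding coordinates as features, tuned by stratified 5-fold CV
over a small grid that includes L1/L2 penalty strengths, with balanced
(inverse-frequency) class weights.  Subtype calls with a maximum class
probability below 0.5 are flagged "Not confident".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, cohen_kappa_score, confusion_matrix, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .datamodel import ValidationError

logger = logging.getLogger(__name__)

NOT_CONFIDENT = "Not confident"

#: Default controlled vocabulary: 27 WHO-2022-style acute leukemia subtypes
#: plus otherwise-normal control.  This is configuration, not clinical logic;
#: callers may supply their own list (e.g. for synthetic cohorts).
DEFAULT_WHO2022_VOCABULARY = (
    "AML with t(8;21); RUNX1::RUNX1T1",
    "AML with inv(16); t(16;16); CBFB::MYH11",
    "APL with t(15;17); PML::RARA",
    "AML with t(v;11q23); KMT2A-r",
    "AML with t(6;9); DEK::NUP214",
    "AML with t(8;16); KAT6A::CREBBP",
    "AML with inv(3); t(3;3); MECOM",
    "AML with NUP98 fusion",
    "AML with mutated NPM1",
    "AML with mutated CEBPA",
    "AML with t(9;22); BCR::ABL1",
    "AML with RBM15::MRTFA",
    "AML with FUS::ERG",
    "AML with CBFA2T3::GLIS2",
    "AML, NOS",
    "MDS-related, secondary myeloid",
    "B-ALL with high hyperdiploidy",
    "B-ALL with hypodiploidy",
    "B-ALL with t(9;22); BCR::ABL1",
    "B-ALL with t(v;11q23); KMT2A-r",
    "B-ALL with t(12;21); ETV6::RUNX1",
    "B-ALL with t(1;19); TCF3::PBX1",
    "B-ALL with iAMP21",
    "B-ALL, NOS",
    "T-ALL",
    "MPAL T-Lymphoblastic/Myeloid",
    "MPAL B-Lymphoblastic/Myeloid",
    "Otherwise-Normal Control",
)

#: Label prefixes treated as myeloid for prognostic-model gating.
MYELOID_PREFIXES = ("AML", "APL", "MDS")


def default_myeloid_labels(vocabulary=DEFAULT_WHO2022_VOCABULARY) -> frozenset:
    return frozenset(l for l in vocabulary if l.startswith(MYELOID_PREFIXES))


@dataclass
class SubtypePrediction:
    sample_id: str
    class_probabilities: pd.Series  # label -> probability, sums to 1
    top_label: str
    second_label: str
    confident: bool

    @property
    def reported_label(self) -> str:
        return self.top_label if self.confident else NOT_CONFIDENT


@dataclass
class RiskPrediction:
    sample_id: str
    p_death_5y: float
    group: str  # "high" | "low"


def _default_grid() -> dict:
    # small fixed grid: tree count, leaf count, L1 and L2 penalty strengths
    return {
        "n_estimators": [100, 300],
        "num_leaves": [7, 31],
        "reg_alpha": [0.0, 1.0],
        "reg_lambda": [0.0, 1.0],
    }


def _lgbm_params(seed: int) -> dict:
    # deterministic single-threaded boosting so fixed seeds reproduce bit-for-bit
    return dict(
        learning_rate=0.1,
        class_weight="balanced",
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


class SubtypeClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest gradient-boosted subtype classifier on 5 embedding coordinates.

    Parameters
    ----------
    vocabulary : sequence of str or None
        Controlled label list; labels outside it are rejected.  ``None``
        accepts the labels observed at fit time.
    seed : int
        Seed for boosting and CV fold shuffling.
    confidence_threshold : float
        Maximum-probability gate below which a call is "Not confident".
    """

    def __init__(self, vocabulary=None, seed: int = 0, cv_folds: int = 5,
                 param_grid: dict | None = None, confidence_threshold: float = 0.5):
        self.vocabulary = vocabulary
        self.seed = seed
        self.cv_folds = cv_folds
        self.param_grid = param_grid
        self.confidence_threshold = confidence_threshold

    def fit(self, X, y):
        from lightgbm import LGBMClassifier

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if self.vocabulary is not None:
            unknown = sorted(set(y) - set(self.vocabulary))
            if unknown:
                raise ValidationError(f"labels outside the vocabulary: {unknown[:5]}")
        counts = pd.Series(y).value_counts()
        tiny = counts.index[counts < 2].tolist()
        if tiny:
            raise ValidationError(f"class(es) with a single sample: {tiny}")
        if counts.size == 1:
            # degenerate one-class cohort: constant predictor
            self.model_ = None
            self.classes_ = np.asarray([counts.index[0]], dtype=object)
            self.cv_results_ = {"best_params": {}, "best_cv_accuracy": 1.0}
            self.n_features_in_ = X.shape[1]
            return self
        # one-vs-rest boosting; lightgbm requires the binary objective when
        # only two classes are present (equivalent model)
        objective = "multiclassova" if counts.size > 2 else "binary"
        base = LGBMClassifier(objective=objective, **_lgbm_params(self.seed))
        grid = self.param_grid or _default_grid()
        cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(base, grid, cv=cv, scoring="accuracy", n_jobs=1, refit=True)
        search.fit(X, y)
        self.model_ = search.best_estimator_
        self.classes_ = self.model_.classes_
        self.cv_results_ = {
            "best_params": search.best_params_,
            "best_cv_accuracy": float(search.best_score_),
        }
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} coordinates per sample, got shape {X.shape}"
            )
        if self.model_ is None:
            return np.ones((X.shape[0], 1))
        probs = self.model_.predict_proba(X)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def predict_subtypes(self, X, sample_ids=None) -> list:
        """Full predictions with confidence gating and second-likely call."""
        probs = self.predict_proba(X)
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(probs.shape[0])]
        out = []
        for sid, p in zip(sample_ids, probs):
            order = np.argsort(p)[::-1]
            series = pd.Series(p, index=self.classes_)
            out.append(SubtypePrediction(
                sample_id=str(sid),
                class_probabilities=series,
                top_label=str(self.classes_[order[0]]),
                second_label=str(self.classes_[order[1]]) if len(p) > 1 else "",
                confident=bool(p[order[0]] >= self.confidence_threshold),
            ))
        return out


class MortalityRiskClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier of death within a fixed horizon (default 60 months).

    Training labels follow the dead/alive rule: dead if the event occurred at
    or before the horizon; alive if followed beyond the horizon; samples
    censored before the horizon have an undefined label and are excluded from
    training (but still receive predictions at inference).
    """

    def __init__(self, horizon_months: float = 60.0, seed: int = 0, cv_folds: int = 5,
                 param_grid: dict | None = None, cutoff: float = 0.5):
        self.horizon_months = horizon_months
        self.seed = seed
        self.cv_folds = cv_folds
        self.param_grid = param_grid
        self.cutoff = cutoff

    @staticmethod
    def horizon_labels(time, event, horizon: float):
        """Return (labels, usable_mask): 1=dead by horizon, 0=alive past it."""
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        dead = (event == 1) & (time <= horizon)
        alive = time >= horizon
        usable = dead | alive
        labels = np.where(dead, 1, 0)
        return labels, usable

    def fit(self, X, time, event):
        from lightgbm import LGBMClassifier

        X = np.asarray(X, dtype=float)
        labels, usable = self.horizon_labels(time, event, self.horizon_months)
        n_excluded = int((~usable).sum())
        if n_excluded:
            logger.info("excluded %d sample(s) censored before the %.0f-month horizon",
                        n_excluded, self.horizon_months)
        y = labels[usable]
        Xu = X[usable]
        counts = pd.Series(y).value_counts()
        if counts.min() < 10 or counts.size < 2:
            raise ValidationError(
                f"need >=10 samples per outcome class, got {counts.to_dict()}"
            )
        base = LGBMClassifier(objective="binary", **_lgbm_params(self.seed))
        grid = self.param_grid or _default_grid()
        cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(base, grid, cv=cv, scoring="roc_auc", n_jobs=1, refit=True)
        search.fit(Xu, y)
        self.model_ = search.best_estimator_
        self.classes_ = np.array([0, 1])
        self.cv_results_ = {
            "best_params": search.best_params_,
            "best_cv_auc": float(search.best_score_),
        }
        self.n_excluded_ = n_excluded
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.cutoff).astype(int)

    def predict_risk(self, X, sample_ids=None) -> list:
        p = self.predict_proba(X)[:, 1]
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(len(p))]
        return [
            RiskPrediction(str(s), float(pi), "high" if pi >= self.cutoff else "low")
            for s, pi in zip(sample_ids, p)
        ]


def train_subtype(coords5, labels, seed: int = 0, **kwargs) -> SubtypeClassifier:
    return SubtypeClassifier(seed=seed, **kwargs).fit(coords5, labels)


def predict_subtype(model: SubtypeClassifier, coords5, sample_ids=None) -> list:
    return model.predict_subtypes(coords5, sample_ids=sample_ids)


def train_risk(coords5, os_time, os_event, horizon_months: float = 60.0,
               seed: int = 0, **kwargs) -> MortalityRiskClassifier:
    return MortalityRiskClassifier(horizon_months=horizon_months, seed=seed,
                                   **kwargs).fit(coords5, os_time, os_event)


def metrics(true_labels, predicted_labels, labels=None) -> dict:
    """Accuracy, weighted F1, Cohen's kappa, per-class concordance, and the
    row-normalized confusion matrix.

    Per-class concordance is the diagonal of the row-normalized confusion
    matrix, i.e. per-class recall.
    """
    y_true = np.asarray(true_labels, dtype=object)
    y_pred = np.asarray(predicted_labels, dtype=object)
    if len(y_true) == 0:
        raise ValidationError("empty input")
    if len(y_true) != len(y_pred):
        raise ValidationError("label vectors differ in length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=labels).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, cm / row_sums, np.nan)
    per_class = pd.Series(np.diag(norm), index=labels)
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "weighted_f1": float(f1_score(y_true, y_pred, average="weighted",
                                      labels=labels, zero_division=0)),
        "cohens_kappa": float(cohen_kappa_score(y_true, y_pred, labels=labels)),
        "per_class_concordance": per_class,
        "normalized_confusion": pd.DataFrame(norm, index=labels, columns=labels),
    }
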