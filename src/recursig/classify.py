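"""Recurrence classifiers with repeated stratified cross-validation.

Models are trained on z-scored expression of the signature genes in one
cohort (5 repeats of stratified 10-fold CV with an internal hyperparameter
grid) and validated on other cohorts.  AUC is the Mann-Whitney rank
statistic (ties count 0.5) and its confidence interval uses the DeLong
placement-variance method.

The linear max-margin model (linear-kernel SVM) is the reference
algorithm; radial-kernel SVM, random forest and a small neural network are
available behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort import ExpressionCohort


class ClassifierError(ValueError):
    pass


ALGORITHMS = ("linear_margin", "radial_margin", "random_forest", "neural_net")

#: regularization strength grid for margin models (7 points, log scale)
C_GRID = np.logspace(-3, 3, 7)


@dataclass
class ModelSpec:
    features: Sequence[str]
    algorithm: str = "linear_margin"
    repeats: int = 5
    folds: int = 10
    metric: str = "roc_auc"  # sklearn scoring name; "ROC" selection
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ClassifierError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_pos: int
    n_neg: int


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    cv_auc: float
    best_params: dict
    train_cohort: str


def _estimator_and_grid(spec: ModelSpec):
    if spec.algorithm == "linear_margin":
        return SVC(kernel="linear", random_state=spec.seed), {"C": C_GRID}
    if spec.algorithm == "radial_margin":
        return SVC(kernel="rbf", random_state=spec.seed), {"C": C_GRID, "gamma": ["scale", 0.1, 1.0]}
    if spec.algorithm == "random_forest":
        return (RandomForestClassifier(random_state=spec.seed),
                {"max_features": [1, "sqrt", None]})
    return (MLPClassifier(hidden_layer_sizes=(4,), max_iter=2000, random_state=spec.seed),
            {"alpha": [1e-4, 1e-2, 1.0]})


def _design(cohort: ExpressionCohort, features: Sequence[str]):
    missing = [g for g in features if g not in cohort.values.index]
    if missing:
        raise ClassifierError(f"feature(s) missing in cohort {cohort.name}: {missing}")
    labels = cohort.recurrence_labels()
    known = labels.isin(["recurrence", "norecurrence"])
    y = (labels[known] == "recurrence").astype(int).to_numpy()
    X = cohort.values.loc[list(features), known[known].index].to_numpy(dtype=float).T
    return X, y


def train_recurrence_model(cohort: ExpressionCohort, spec: ModelSpec) -> TrainedModel:
    """Hyperparameter selection by mean CV AUC over repeated stratified
    folds, then a final refit on the full training cohort."""
    X, y = _design(cohort, spec.features)
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == 0)))
    if n_min < spec.folds:
        raise ClassifierError(
            f"class too small for {spec.folds}-fold stratification (min class {n_min})"
        )
    est, grid = _estimator_and_grid(spec)
    cv = RepeatedStratifiedKFold(
        n_splits=spec.folds, n_repeats=spec.repeats, random_state=spec.seed
    )
    search = GridSearchCV(est, grid, scoring=spec.metric, cv=cv, n_jobs=None)
    search.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=search.best_estimator_,
        cv_auc=float(search.best_score_),
        best_params=dict(search.best_params_),
        train_cohort=cohort.name,
    )


def decision_scores(model: TrainedModel, cohort: ExpressionCohort) -> tuple[np.ndarray, np.ndarray]:
    X, y = _design(cohort, model.spec.features)
    est = model.estimator
    if hasattr(est, "decision_function"):
        scores = est.decision_function(X)
    else:
        scores = est.predict_proba(X)[:, 1]
    return np.asarray(scores, dtype=float), y


def auc_mann_whitney(scores, labels) -> float:
    """AUC by midrank comparison; ties between classes count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ClassifierError("both classes required for AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> AUCResult:
    """AUC with the DeLong placement-variance confidence interval,
    truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ClassifierError("both classes required for AUC")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # placements: V10 (per positive), V01 (per negative)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    return AUCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        method="delong",
        n_pos=m,
        n_neg=n,
    )


def evaluate_auc_ci(model: TrainedModel, cohort: ExpressionCohort) -> AUCResult:
    """External-validation AUC of a trained model on another cohort."""
    if cohort.name == model.train_cohort:
        raise ClassifierError("evaluation cohort must differ from the training cohort")
    scores, y = decision_scores(model, cohort)
    return delong_auc_ci(scores, y)


def cross_cohort_validate(
    train: ExpressionCohort, tests: Sequence[ExpressionCohort], spec: ModelSpec
) -> dict[str, AUCResult]:
    """Train on one cohort, report one AUCResult per test cohort."""
    model = train_recurrence_model(train, spec)
    return {t.name: evaluate_auc_ci(model, t) for t in tests}
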