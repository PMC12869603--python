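"""Therapy-response classification from subnetwork topology features.

Patients are labelled responders when their relative motor improvement

    dUPDRS-III = (UPDRS_baseline - UPDRS_followup) / UPDRS_baseline * 100

reaches the clinically meaningful 15% boundary (inclusive).  Classification
runs a nested leave-one-out scheme: each subject is held out once, and the
training portion alone drives both feature standardization and the inner
5-fold grid search over hyperparameters.  Threshold-free metrics (ROC-AUC,
PR-AUC) are computed on the pooled held-out scores, since single-subject
outer folds admit no per-fold AUC.  Significance comes from re-running the
entire nested pipeline under label permutations; the three headline metrics
are Benjamini-Hochberg corrected as one family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, average_precision_score,
                             confusion_matrix, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .connectome import FPConnError
from .differential import bh_adjust

logger = logging.getLogger(__name__)

RESPONDER_THRESHOLD_PERCENT = 15.0

_TREE_FAMILIES = {"random_forest", "gradient_boosting", "decision_tree"}

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"clf__n_estimators": [100, 300],
                      "clf__max_depth": [None, 3, 5]},
    "gradient_boosting": {"clf__learning_rate": [0.05, 0.1],
                          "clf__n_estimators": [100, 300],
                          "clf__max_depth": [2, 3]},
    "k_nearest_neighbors": {"clf__n_neighbors": [3, 5, 7],
                            "clf__weights": ["uniform", "distance"]},
    "logistic_regression": {"clf__C": [0.1, 1.0, 10.0]},
    "support_vector_machine": {"clf__C": [0.1, 1.0, 10.0],
                               "clf__kernel": ["linear", "rbf"]},
    "decision_tree": {"clf__max_depth": [None, 2, 3, 5]},
}


@dataclass
class ModelSpec:
    family: str = "random_forest"
    grid: dict[str, list] | None = None
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _DEFAULT_GRIDS:
            raise FPConnError(f"unknown model family {self.family!r}")
        if self.grid is None:
            self.grid = dict(_DEFAULT_GRIDS[self.family])
        if not self.grid:
            raise FPConnError("hyperparameter grid must be nonempty")
        if self.inner_folds < 2:
            raise FPConnError("inner_folds must be >= 2")

    @property
    def tree_based(self) -> bool:
        return self.family in _TREE_FAMILIES

    def make_estimator(self) -> Pipeline:
        seed = self.seed
        makers = {
            "random_forest": lambda: RandomForestClassifier(random_state=seed),
            "gradient_boosting": lambda: GradientBoostingClassifier(
                random_state=seed),
            "k_nearest_neighbors": lambda: KNeighborsClassifier(),
            "logistic_regression": lambda: LogisticRegression(
                max_iter=5000, random_state=seed),
            "support_vector_machine": lambda: SVC(random_state=seed),
            "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        }
        return Pipeline([("scale", StandardScaler()),
                         ("clf", makers[self.family]())])


@dataclass
class CVReport:
    per_fold_predictions: pd.DataFrame
    metrics: dict[str, float]
    confusion_matrix: np.ndarray
    importances: pd.Series | None
    feature_names: tuple[str, ...]
    seed: int


@dataclass
class PermutationSignificance:
    observed: dict[str, float]
    null_distributions: dict[str, np.ndarray] = field(repr=False)
    p_raw: dict[str, float] = field(default_factory=dict)
    p_adj: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0
    seed: int = 0


def label_responders(clinical: pd.DataFrame,
                     threshold_percent: float = RESPONDER_THRESHOLD_PERCENT,
                     ) -> pd.DataFrame:
    """Add relative UPDRS-III improvement and the responder label.

    The boundary is inclusive: improvement >= ``threshold_percent`` counts
    as clinically meaningful response.
    """
    out = clinical.copy()
    bl = out["updrs_bl"].to_numpy(dtype=float)
    if np.any(bl <= 0):
        bad = out.loc[bl <= 0, "subject_id"].iloc[0]
        raise FPConnError(f"non-positive baseline UPDRS-III for subject {bad}")
    fu = out["updrs_fu"].to_numpy(dtype=float)
    out["delta_percent"] = (bl - fu) / bl * 100.0
    out["responder"] = out["delta_percent"] >= threshold_percent
    return out


def _grid_size(grid: dict[str, list]) -> int:
    size = 1
    for v in grid.values():
        size *= len(v)
    return size


def _score_of(model, x: np.ndarray) -> float:
    if hasattr(model, "predict_proba"):
        return float(model.predict_proba(x)[0, 1])
    return float(model.decision_function(x)[0])


def nested_loocv_classify(features: pd.DataFrame, labels: pd.Series,
                          spec: ModelSpec) -> CVReport:
    """Nested leave-one-out classification with inner grid search.

    ``features`` is subjects x measures (index = subject id); ``labels`` is
    a boolean/int series aligned on the same index.  Standardization and
    hyperparameter selection are refit inside every outer fold from the
    training subjects only.
    """
    x = features.to_numpy(dtype=float)
    y = labels.loc[features.index].to_numpy(dtype=int)
    n = len(y)
    if n < 6:
        raise FPConnError(f"need >= 6 subjects for nested LOOCV, got {n}")
    if len(np.unique(y)) < 2:
        raise FPConnError("both classes must be present")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    fold_importances = []
    fold_conf = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise FPConnError("single-class training fold; cannot fit")
        model = spec.make_estimator()
        if _grid_size(spec.grid) > 1:
            min_class = int(np.bincount(y_tr).min())
            folds = min(spec.inner_folds, min_class)
            if folds < spec.inner_folds:
                logger.info("inner folds reduced to %d (class counts)", folds)
            if folds < 2:
                raise FPConnError("too few per-class subjects for inner CV")
            inner = StratifiedKFold(n_splits=folds, shuffle=True,
                                    random_state=spec.seed)
            search = GridSearchCV(model, spec.grid, cv=inner,
                                  scoring="accuracy", n_jobs=None)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(x[train], y_tr)
            fitted = search.best_estimator_
        else:
            params = {k: v[0] for k, v in spec.grid.items()}
            model.set_params(**params)
            fitted = model.fit(x[train], y_tr)
        preds[i] = int(fitted.predict(x[i:i + 1])[0])
        scores[i] = _score_of(fitted, x[i:i + 1])
        fold_conf.append(confusion_matrix(y[i:i + 1], preds[i:i + 1],
                                          labels=[0, 1]))
        if spec.tree_based:
            fold_importances.append(fitted.named_steps["clf"].feature_importances_)
    metrics = {
        "accuracy": float(accuracy_score(y, preds)),
        "precision": float(precision_score(y, preds, zero_division=0)),
        "recall": float(recall_score(y, preds, zero_division=0)),
        "f1": float(f1_score(y, preds, zero_division=0)),
        "roc_auc": float(roc_auc_score(y, scores)),
        "pr_auc": float(average_precision_score(y, scores)),
    }
    importances = None
    if fold_importances:
        importances = pd.Series(np.mean(fold_importances, axis=0),
                                index=features.columns)
    per_fold = pd.DataFrame({"subject_id": features.index,
                             "true": y, "pred": preds, "score": scores})
    return CVReport(per_fold_predictions=per_fold, metrics=metrics,
                    confusion_matrix=np.mean(fold_conf, axis=0),
                    importances=importances,
                    feature_names=tuple(features.columns), seed=spec.seed)


def permutation_significance(features: pd.DataFrame, labels: pd.Series,
                             spec: ModelSpec, n_perm: int = 1000,
                             seed: int = 0) -> PermutationSignificance:
    """Label-permutation null for accuracy, ROC-AUC and PR-AUC.

    Each iteration permutes the responder labels and repeats the full nested
    LOOCV pipeline; one-sided plus-one-corrected p-values are BH-adjusted
    across the three metrics.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: permutation p-values are coarse")
    observed = nested_loocv_classify(features, labels, spec).metrics
    keys = ("accuracy", "roc_auc", "pr_auc")
    rng = np.random.default_rng(seed)
    nulls = {k: np.empty(n_perm) for k in keys}
    y = labels.loc[features.index].to_numpy()
    for b in range(n_perm):
        perm = pd.Series(rng.permutation(y), index=features.index)
        try:
            m = nested_loocv_classify(features, perm, spec).metrics
        except FPConnError:
            m = {k: np.nan for k in keys}
        for k in keys:
            nulls[k][b] = m[k]
    p_raw = {}
    for k in keys:
        vals = nulls[k][~np.isnan(nulls[k])]
        p_raw[k] = (1 + int(np.sum(vals >= observed[k]))) / (len(vals) + 1)
    adj = bh_adjust(np.array([p_raw[k] for k in keys]))
    p_adj = {k: float(a) for k, a in zip(keys, adj)}
    return PermutationSignificance(
        observed={k: observed[k] for k in keys},
        null_distributions=nulls, p_raw=p_raw, p_adj=p_adj,
        n_perm=n_perm, seed=seed)


def feature_importance_summary(report: CVReport) -> pd.Series:
    """Fold-averaged mean-decrease-in-impurity shares, ranked descending.

    Shares are normalized to sum to one; ties break alphabetically by
    feature name.  Only defined for tree-based model families.
    """
    if report.importances is None:
        raise FPConnError("importance undefined for family (not tree-based)")
    imp = report.importances
    total = imp.sum()
    shares = imp / total if total > 0 else imp * 0 + 1.0 / len(imp)
    order = sorted(shares.index, key=lambda name: (-shares[name], name))
    return shares.loc[order]
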