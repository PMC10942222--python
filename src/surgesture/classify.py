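"""Cross-validated skill classification and feature-importance mining.

Five classical model families — logistic regression, RBF-kernel SVM,
random forest, gradient-boosted trees, AdaBoost — are trained under
surgeon-grouped, approximately class-stratified five-fold cross-validation
to separate competent from incompetent performance, for the overall skill
label and for each mGOALS item.  Grouping all of a surgeon's videos into
one fold prevents the classifier from recognising the surgeon rather than
the skill.  Feature standardization is fit on the training fold only, and
any minority-class augmentation likewise happens strictly inside the
training fold.

ROC/AUC is computed in-package via the midrank (Mann–Whitney) form:
AUC = U / (n_pos * n_neg), identical to the trapezoidal area under the ROC
curve with tied scores handled by midranks.

Hyperparameters are fixed, documented defaults rather than tuned values:
logistic L2 with C=1; SVM RBF with C=1 and gamma scaled by feature
variance; 500-tree random forest; 100-tree depth-3 gradient boosting at
learning rate 0.1; AdaBoost over 100 decision stumps.  All are
overridable through the params object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .augment import AugmentParams, balance_classes
from .features import feature_columns, feature_matrix
from .taxonomy import Taxonomy
from .timeline import CaseTimeline

log = logging.getLogger(__name__)

MODEL_NAMES = ("logistic", "svm_rbf", "random_forest",
               "gradient_boosted_trees", "adaptive_boosting")
OVERALL_TARGET = "overall"


class ClassifierError(ValueError):
    """Raised for degenerate classification inputs."""


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via midranks (tie-aware Mann–Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ClassifierError("scores and labels must be equal-length vectors")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def grouped_stratified_folds(labels, surgeon_ids, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per video: surgeon-grouped, approximately class-balanced.

    All videos by one surgeon share a fold.  Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    surgeon_ids = np.asarray(surgeon_ids)
    n_surgeons = len(set(surgeon_ids.tolist()))
    if k > n_surgeons:
        raise ClassifierError(f"k={k} folds exceed {n_surgeons} surgeons")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(labels), -1, dtype=int)
    for fold, (_, test_idx) in enumerate(
            splitter.split(np.zeros((len(labels), 1)), labels, groups=surgeon_ids)):
        folds[test_idx] = fold
    assert (folds >= 0).all()
    return folds


def _make_model(name: str, seed: int, hyperparams: dict | None = None):
    hp = dict(hyperparams or {})
    if name == "logistic":
        return LogisticRegression(C=hp.pop("C", 1.0), max_iter=5000, **hp)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), **hp)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=hp.pop("n_estimators", 500),
                                      random_state=seed, **hp)
    if name == "gradient_boosted_trees":
        return GradientBoostingClassifier(n_estimators=hp.pop("n_estimators", 100),
                                          max_depth=hp.pop("max_depth", 3),
                                          learning_rate=hp.pop("learning_rate", 0.1),
                                          random_state=seed, **hp)
    if name == "adaptive_boosting":
        return AdaBoostClassifier(n_estimators=hp.pop("n_estimators", 100),
                                  random_state=seed, **hp)
    raise ClassifierError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass(frozen=True)
class CVParams:
    k: int = 5
    seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES
    hyperparams: dict = dc_field(default_factory=dict)  # model name -> overrides
    augment: AugmentParams | None = None


@dataclass
class CellResult:
    """One model x target cell of the cross-validation grid."""

    model: str
    target: str
    fold_aucs: list[float]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    skipped_folds: list[int]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.pooled_scores, self.pooled_labels)


@dataclass
class ClassificationReport:
    cells: dict[tuple[str, str], CellResult]
    folds: np.ndarray
    seed: int

    def mean_auc(self, model: str, target: str = OVERALL_TARGET) -> float:
        return self.cells[(model, target)].mean_auc

    def best_model(self, target: str = OVERALL_TARGET) -> tuple[str, float]:
        cands = [(c.mean_auc, m) for (m, t), c in self.cells.items() if t == target]
        auc, model = max(cands)
        return model, auc

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": c.model, "target": c.target, "mean_auc": c.mean_auc,
                 "pooled_auc": c.pooled_auc,
                 **{f"fold{i}_auc": a for i, a in enumerate(c.fold_aucs)}}
                for c in self.cells.values()]
        return pd.DataFrame(rows).sort_values(["target", "model"]).reset_index(drop=True)


def run_cv(features: pd.DataFrame, targets: dict[str, np.ndarray], params: CVParams,
           cases: list[CaseTimeline] | None = None,
           taxonomy: Taxonomy | None = None) -> ClassificationReport:
    """Five-fold surgeon-grouped cross-validation over models x targets.

    ``features`` is a :func:`~surgesture.features.feature_matrix` table
    (surgeon_id column + feature columns).  ``targets`` maps target names
    to per-video 0/1 labels aligned with the rows.  When ``params.augment``
    is set, ``cases`` and ``taxonomy`` must be given (aligned with the
    rows) so minority oversampling can regenerate features from perturbed
    timelines inside each training fold.

    Folds where the held-out videos are single-class are skipped and
    logged; the cell averages over the remaining folds.
    """
    cols = feature_columns(features)
    surgeon_ids = features["surgeon_id"].to_numpy()
    X_all = features.loc[:, cols].to_numpy(dtype=float)
    if params.augment is not None and (cases is None or taxonomy is None):
        raise ClassifierError("augmentation requires the timelines and taxonomy")
    if cases is not None and len(cases) != len(features):
        raise ClassifierError("cases must align with feature rows")

    primary = targets.get(OVERALL_TARGET, next(iter(targets.values())))
    folds = grouped_stratified_folds(primary, surgeon_ids, k=params.k, seed=params.seed)

    cells: dict[tuple[str, str], CellResult] = {}
    for target_name, y in targets.items():
        y = np.asarray(y, dtype=int)
        if len(set(y.tolist())) < 2:
            raise ClassifierError(f"target {target_name!r} is single-class")
        per_model: dict[str, dict] = {
            m: {"aucs": [], "skipped": [], "s": [], "y": []} for m in params.models}
        for fold in range(params.k):
            test = folds == fold
            train = ~test
            y_tr, y_te = y[train], y[test]
            if len(set(y_te.tolist())) < 2 or len(set(y_tr.tolist())) < 2:
                log.warning("target %s: fold %d single-class; skipped", target_name, fold)
                for m in params.models:
                    per_model[m]["skipped"].append(fold)
                continue
            X_tr = X_all[train]
            if params.augment is not None:
                tr_cases = [c for c, t in zip(cases, train) if t]
                aug_cases, y_tr, _ = balance_classes(tr_cases, y_tr, params.augment)
                X_tr = feature_matrix(aug_cases, taxonomy).loc[:, cols].to_numpy(float)
            scaler = StandardScaler().fit(X_tr)
            X_tr_s = scaler.transform(X_tr)
            X_te_s = scaler.transform(X_all[test])
            for model_name in params.models:
                model = _make_model(model_name, params.seed,
                                    params.hyperparams.get(model_name))
                model.fit(X_tr_s, y_tr)
                s = _decision_scores(model, X_te_s)
                per_model[model_name]["aucs"].append(roc_auc(s, y_te))
                per_model[model_name]["s"].append(s)
                per_model[model_name]["y"].append(y_te)
        for model_name, acc in per_model.items():
            if not acc["aucs"]:
                raise ClassifierError(
                    f"target {target_name!r}, model {model_name!r}: every fold degenerate")
            cells[(model_name, target_name)] = CellResult(
                model=model_name, target=target_name, fold_aucs=acc["aucs"],
                pooled_scores=np.concatenate(acc["s"]),
                pooled_labels=np.concatenate(acc["y"]),
                skipped_folds=acc["skipped"])
    return ClassificationReport(cells=cells, folds=folds, seed=params.seed)


@dataclass(frozen=True)
class ImportanceReport:
    model: str
    target: str
    method: str
    scores: pd.Series          # normalized, sums to 1
    top10: pd.Series           # descending, ties broken by feature name

    def __post_init__(self) -> None:
        assert abs(float(self.scores.sum()) - 1.0) < 1e-9


def feature_importance(features: pd.DataFrame, labels, model_name: str,
                       method: str = "permutation", n_repeats: int = 10,
                       seed: int = 0, target: str = OVERALL_TARGET,
                       hyperparams: dict | None = None) -> ImportanceReport:
    """Normalized feature scores and the top-10 list for one model.

    ``native`` uses |coefficients| for the linear model and impurity
    importances for tree ensembles (unavailable for the RBF SVM).
    ``permutation`` measures the mean AUC drop over ``n_repeats`` shuffles
    of each column, floored at 0 — comparable across all model families.
    Scores are normalized to sum to 1; an all-zero profile becomes uniform.
    """
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ClassifierError("feature importance needs both classes")
    cols = feature_columns(features)
    X = StandardScaler().fit_transform(features.loc[:, cols].to_numpy(dtype=float))
    model = _make_model(model_name, seed, hyperparams)
    model.fit(X, labels)

    if method == "native":
        if hasattr(model, "coef_"):
            raw = np.abs(model.coef_).ravel()
        elif hasattr(model, "feature_importances_"):
            raw = np.asarray(model.feature_importances_, dtype=float)
        else:
            raise ClassifierError(f"model {model_name!r} exposes no native importances; "
                                  "use method='permutation'")
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        base = roc_auc(_decision_scores(model, X), labels)
        raw = np.zeros(len(cols))
        for j in range(len(cols)):
            drops = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(base - roc_auc(_decision_scores(model, Xp), labels))
            raw[j] = max(0.0, float(np.mean(drops)))
    else:
        raise ClassifierError(f"unknown importance method {method!r}")

    total = raw.sum()
    norm = raw / total if total > 0 else np.full(len(cols), 1.0 / len(cols))
    scores = pd.Series(norm, index=cols, name="importance")
    order = sorted(cols, key=lambda c: (-scores[c], c))
    top10 = scores.loc[order[:10]]
    return ImportanceReport(model=model_name, target=target, method=method,
                            scores=scores, top10=top10)
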