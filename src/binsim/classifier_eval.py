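"""Supervised benchmark: RF and PLS-DA with repeated stratified CV,
permutation tests, ROC, and feature-importance occurrence profiling.

Accuracy is estimated by stratified k-fold cross-validation repeated with
fresh shuffles; significance by permutation of the class labels.  Feature
importance (Gini for random forests, VIP for PLS-DA) is averaged over the
cross-validation refits, the top fraction retained, and the selected
features profiled by how many samples and classes they occur in -- the
signature that separates biomarker-type (class-exclusive) features from
broadly detected ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "PLSDAClassifier",
    "CVResult",
    "PermutationResult",
    "ImportanceTable",
    "OccurrenceProfile",
    "cv_accuracy",
    "fit_rf",
    "fit_plsda",
    "choose_components",
    "gini_importance",
    "vip",
    "cv_importance",
    "top_fraction",
    "occurrence_profile",
    "importance_overlap",
    "permutation_test",
    "roc_curve",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Protocol for one benchmark cell: model family + CV layout."""

    kind: str = "random_forest"       # random_forest | plsda
    rf_trees: int = 100
    pls_components: int | str = "auto"
    n_folds: int = 3
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "plsda"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.pls_components != "auto" and int(self.pls_components) < 1:
            raise ValueError("pls_components must be >= 1 or 'auto'")


@dataclass(frozen=True)
class CVResult:
    """Per-repeat pooled fold accuracies and their summary."""

    per_repeat: np.ndarray
    mean_accuracy: float
    sd_accuracy: float


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float


@dataclass(frozen=True)
class ImportanceTable:
    """Per-feature importance scores (Gini importances sum to 1; VIP scores
    satisfy mean(VIP^2) = 1)."""

    feature_ids: np.ndarray
    scores: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        ids = np.asarray(self.feature_ids)
        sc = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "feature_ids", ids)
        object.__setattr__(self, "scores", sc)
        if ids.shape != sc.shape:
            raise ValueError("feature_ids and scores must align")
        if np.any(sc < 0):
            raise ValueError("importance scores must be non-negative")


@dataclass(frozen=True)
class OccurrenceProfile:
    """Sample- and class-occurrence counts of a feature set."""

    feature_ids: np.ndarray
    sample_counts: np.ndarray
    class_counts: np.ndarray
    median_sample_occurrence: float
    sample_occurrence_range: tuple
    median_class_occurrence: float
    class_occurrence_range: tuple


# --------------------------------------------------------------------------
# Models
# --------------------------------------------------------------------------

class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS-DA: multi-response PLS (NIPALS) on one-hot class targets.

    Two-class problems use a single 0/1 response column with a 0.5 decision
    threshold; multi-class problems use one-hot encoding with an argmax
    decision.  X is not rescaled internally -- data are expected to arrive
    pre-treated.

    Fitted attributes follow the usual PLS notation: ``x_weights_`` (W),
    ``x_scores_`` (T), ``x_loadings_`` (P), ``y_loadings_`` (Q) and
    ``ssy_``, the y-variance explained per component,
    ``ssy_a = sum_k q_ak^2 * t_a' t_a``, which weights the VIP scores.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = X.shape
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA requires at least two classes")
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_samples-1, n_features)"
                f"={min(n - 1, p)}"
            )
        Y = self._encode(y)
        self._pls = PLSRegression(
            n_components=self.n_components, scale=False,
            max_iter=self.max_iter, tol=self.tol,
        )
        self._pls.fit(X, Y)
        self.x_weights_ = self._pls.x_weights_
        self.x_scores_ = self._pls.x_scores_
        self.x_loadings_ = self._pls.x_loadings_
        self.y_loadings_ = self._pls.y_loadings_
        T, Q = self.x_scores_, self.y_loadings_
        self.ssy_ = np.array([
            np.sum(Q[:, a] ** 2) * float(T[:, a] @ T[:, a])
            for a in range(self.n_components)
        ])
        return self

    def _encode(self, y) -> np.ndarray:
        if len(self.classes_) == 2:
            return (np.asarray(y) == self.classes_[1]).astype(float).reshape(-1, 1)
        return np.column_stack([
            (np.asarray(y) == c).astype(float) for c in self.classes_
        ])

    def decision_function(self, X) -> np.ndarray:
        """Predicted continuous Y (one column per class; two-class: one column)."""
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        Y = self.decision_function(X)
        if len(self.classes_) == 2:
            return np.where(Y[:, 0] >= 0.5, self.classes_[1], self.classes_[0])
        return self.classes_[np.argmax(Y, axis=1)]


def fit_rf(X, y, trees: int = 100, seed: int = 0) -> RandomForestClassifier:
    """Fit a random forest (bootstrap, Gini splits, sqrt(p) candidates)."""
    X, _ = _matrix(X)
    model = RandomForestClassifier(n_estimators=trees, random_state=seed)
    model.fit(X, np.asarray(y))
    return model


def fit_plsda(X, y, n_components: int) -> PLSDAClassifier:
    X, _ = _matrix(X)
    return PLSDAClassifier(n_components=n_components).fit(X, np.asarray(y))


def choose_components(X, y, max_components: int = 10, folds: int = 3,
                      seed: int = 0) -> int:
    """Component count maximizing cross-validated Q^2 = 1 - PRESS/TSS on
    one-hot Y.  Returns 1 (with a warning) if no count achieves Q^2 > 0."""
    X, _ = _matrix(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) == 2:
        Y = (y == classes[1]).astype(float).reshape(-1, 1)
    else:
        Y = np.column_stack([(y == c).astype(float) for c in classes])
    n, p = X.shape
    max_components = min(max_components, p)
    best_a, best_q2 = 1, -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for a in range(1, max_components + 1):
        press = 0.0
        tss = 0.0
        feasible = True
        for train, test in splits:
            if a > min(len(train) - 1, p):
                feasible = False
                break
            pls = PLSRegression(n_components=a, scale=False)
            pls.fit(X[train], Y[train])
            pred = pls.predict(X[test])
            press += float(np.sum((Y[test] - pred) ** 2))
            tss += float(np.sum((Y[test] - Y[train].mean(axis=0)) ** 2))
        if not feasible:
            break
        q2 = 1.0 - press / tss
        if q2 > best_q2:
            best_a, best_q2 = a, q2
    if best_q2 <= 0:
        logger.warning("no component count reached Q^2 > 0; defaulting to 1 component")
        return 1
    return best_a


# --------------------------------------------------------------------------
# Cross-validation harness
# --------------------------------------------------------------------------

def _matrix(X):
    """(ndarray, feature ids) from PeakTable / BinaryMatrix / DataFrame / array."""
    if hasattr(X, "data") and hasattr(X, "feature_mz"):
        return np.asarray(X.values, dtype=float), np.asarray(X.feature_mz)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.columns.to_numpy()
    X = np.asarray(X, dtype=float)
    return X, np.arange(X.shape[1])


def _check_fold_feasible(y, n_folds: int) -> None:
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < n_folds={n_folds}; "
            f"use k <= {counts.min()}"
        )


def _make_model(spec: ClassifierSpec, X, y, seed: int):
    if spec.kind == "random_forest":
        return RandomForestClassifier(n_estimators=spec.rf_trees, random_state=seed)
    n_comp = spec.pls_components
    if n_comp == "auto":
        n_comp = choose_components(X, y, seed=spec.seed, folds=spec.n_folds)
    return PLSDAClassifier(n_components=int(n_comp))


def _repeat_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def cv_accuracy(X, y, spec: ClassifierSpec) -> CVResult:
    """Mean accuracy over ``n_repeats`` independently shuffled stratified
    k-fold cross-validations; each repeat pools its held-out predictions."""
    X, _ = _matrix(X)
    y = np.asarray(y)
    _check_fold_feasible(y, spec.n_folds)
    seeds = _repeat_seeds(spec.seed, spec.n_repeats)
    accs = []
    for r in range(spec.n_repeats):
        skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                              random_state=int(seeds[r]))
        correct = 0
        for f, (train, test) in enumerate(skf.split(X, y)):
            model = _make_model(spec, X[train], y[train], seed=int(seeds[r]) + f)
            model.fit(X[train], y[train])
            correct += int(np.sum(model.predict(X[test]) == y[test]))
        accs.append(correct / len(y))
    accs = np.asarray(accs)
    return CVResult(per_repeat=accs, mean_accuracy=float(accs.mean()),
                    sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0)


def permutation_test(X, y, spec: ClassifierSpec, n_perm: int = 500) -> PermutationResult:
    """Compare the observed mean CV accuracy with a label-permutation null.

    Each permutation is scored with a single stratified-CV pass; the
    add-one p-value is (1 + #{null >= observed}) / (n_perm + 1).
    """
    X, _ = _matrix(X)
    y = np.asarray(y)
    observed = cv_accuracy(X, y, spec).mean_accuracy
    rng = np.random.default_rng(spec.seed)
    null_spec = replace(spec, n_repeats=1)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(y))
        nulls[i] = cv_accuracy(
            X, y[perm], replace(null_spec, seed=int(rng.integers(2**31)))
        ).mean_accuracy
    p = (1 + int(np.sum(nulls >= observed))) / (n_perm + 1)
    return PermutationResult(observed_accuracy=observed, null_accuracies=nulls,
                             p_value=p)


def roc_curve(X, y, spec: ClassifierSpec):
    """Pooled out-of-fold ROC for a two-class problem.

    Decision scores (RF: positive-class vote fraction; PLS-DA: predicted y)
    from every held-out fold of every repeat are pooled into one curve;
    the AUC uses the trapezoid rule.

    Returns ``(fpr, tpr, auc_value)``.
    """
    X, _ = _matrix(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ROC analysis requires exactly two classes")
    _check_fold_feasible(y, spec.n_folds)
    pos = classes[1]
    seeds = _repeat_seeds(spec.seed, spec.n_repeats)
    scores, truth = [], []
    for r in range(spec.n_repeats):
        skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                              random_state=int(seeds[r]))
        for f, (train, test) in enumerate(skf.split(X, y)):
            model = _make_model(spec, X[train], y[train], seed=int(seeds[r]) + f)
            model.fit(X[train], y[train])
            if isinstance(model, RandomForestClassifier):
                s = model.predict_proba(X[test])[:, list(model.classes_).index(pos)]
            else:
                s = model.decision_function(X[test])[:, 0]
            scores.append(s)
            truth.append(y[test] == pos)
    scores = np.concatenate(scores)
    truth = np.concatenate(truth)
    fpr, tpr, _ = _sk_roc_curve(truth, scores)
    return fpr, tpr, float(_auc(fpr, tpr))


# --------------------------------------------------------------------------
# Feature importance
# --------------------------------------------------------------------------

def gini_importance(model: RandomForestClassifier, feature_ids=None) -> ImportanceTable:
    """Mean decrease in Gini impurity per feature, normalized to sum 1."""
    scores = np.asarray(model.feature_importances_, dtype=float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    if feature_ids is None:
        feature_ids = np.arange(scores.size)
    return ImportanceTable(np.asarray(feature_ids), scores, kind="gini")


def vip(model: PLSDAClassifier, feature_ids=None) -> ImportanceTable:
    """Variable Importance in Projection.

    ``VIP_j = sqrt(p * sum_a ssy_a (w_aj/||w_a||)^2 / sum_a ssy_a)`` with p
    features; satisfies mean(VIP^2) = 1.
    """
    W = model.x_weights_
    ssy = model.ssy_
    total = ssy.sum()
    if total == 0:
        raise ValueError("VIP undefined: model explains no y-variance")
    p = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    scores = np.sqrt(p * (wnorm2 @ ssy) / total)
    if feature_ids is None:
        feature_ids = np.arange(p)
    return ImportanceTable(np.asarray(feature_ids), scores, kind="vip")


def cv_importance(X, y, spec: ClassifierSpec) -> ImportanceTable:
    """Importance scores averaged over the training-fold refits of
    ``n_repeats`` cross-validation repeats."""
    Xv, feature_ids = _matrix(X)
    y = np.asarray(y)
    _check_fold_feasible(y, spec.n_folds)
    seeds = _repeat_seeds(spec.seed, spec.n_repeats)
    acc = np.zeros(Xv.shape[1])
    count = 0
    kind = "gini" if spec.kind == "random_forest" else "vip"
    for r in range(spec.n_repeats):
        skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                              random_state=int(seeds[r]))
        for f, (train, _) in enumerate(skf.split(Xv, y)):
            model = _make_model(spec, Xv[train], y[train], seed=int(seeds[r]) + f)
            model.fit(Xv[train], y[train])
            table = (gini_importance(model) if kind == "gini" else vip(model))
            acc += table.scores
            count += 1
    return ImportanceTable(np.asarray(feature_ids), acc / count, kind=kind)


def top_fraction(imp: ImportanceTable, fraction: float = 0.02) -> np.ndarray:
    """The ceil(fraction * p) highest-scoring features.

    Ties are broken by ascending feature id (m/z), so the selection is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    p = imp.scores.size
    k = math.ceil(fraction * p)
    order = np.lexsort((imp.feature_ids, -imp.scores))
    return imp.feature_ids[order[:k]]


def occurrence_profile(features, pt, gt) -> OccurrenceProfile:
    """Sample- and class-occurrence counts of a selected feature set.

    ``pt`` is the original (pre-BinSim) peak table whose gaps define
    occurrence; ``gt`` maps sample id to class.
    """
    gt = dict(gt)
    features = np.asarray(features)
    table_ids = np.asarray(pt.feature_mz)
    idx = []
    for f in features:
        matches = np.flatnonzero(table_ids == f)
        if matches.size == 0:
            raise ValueError(f"feature {f!r} not present in the peak table")
        idx.append(int(matches[0]))
    observed = pt.data.notna().iloc[:, idx]
    sample_counts = observed.sum(axis=0).to_numpy()
    labels = pd.Series({s: gt[s] for s in pt.sample_ids})
    class_counts = observed.groupby(labels, observed=True).any().sum(axis=0).to_numpy()
    return OccurrenceProfile(
        feature_ids=features,
        sample_counts=sample_counts,
        class_counts=class_counts,
        median_sample_occurrence=float(np.median(sample_counts)),
        sample_occurrence_range=(int(sample_counts.min()), int(sample_counts.max())),
        median_class_occurrence=float(np.median(class_counts)),
        class_occurrence_range=(int(class_counts.min()), int(class_counts.max())),
    )


def importance_overlap(sets: dict) -> dict:
    """Venn-region cardinalities of several top-feature sets.

    Returns ``{"regions": {tuple-of-set-names: count}, "unique": {name: count}}``
    where each feature of the union is assigned to the region given by the
    exact combination of sets containing it.
    """
    if len(sets) < 2:
        raise ValueError("overlap requires at least two feature sets")
    names = list(sets)
    as_sets = {k: set(np.asarray(list(v)).tolist()) for k, v in sets.items()}
    regions: dict = {}
    for f in set().union(*as_sets.values()):
        sig = tuple(sorted(k for k in names if f in as_sets[k]))
        regions[sig] = regions.get(sig, 0) + 1
    unique = {k: regions.get((k,), 0) for k in names}
    return {"regions": regions, "unique": unique}
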