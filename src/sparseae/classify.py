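"""Class-weighted random-forest validation of marker sets.

Class weights follow w_v = n / (k * n_v) (inverse class frequency), and the
weighted Gini impurity of a tree node with class proportions p_v is

    G = 1 - sum_v w_v * p_v^2

which reduces to the ordinary Gini impurity when every w_v = 1. The default
forest is scikit-learn's RandomForestClassifier with these class weights
(its impurity reweights the proportions themselves, the standard CART
weighting); ``impurity="literal"`` instead uses the bundled small forest
whose split criterion is the literal formula above. The two differ whenever
weights != 1; both are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .autoencoder import MarkerSet
from .preprocess import ExpressionMatrix, SubtypeLabelSet


@dataclass
class ClassWeights:
    """w_v = n / (k * n_v); satisfies sum_v w_v * n_v = n exactly."""

    weights: dict[str, float]
    n: int
    k: int


def class_weights(labels: SubtypeLabelSet | Mapping[str, int]) -> ClassWeights:
    counts = (
        labels.class_counts if isinstance(labels, SubtypeLabelSet) else dict(labels)
    )
    if not counts:
        raise ValueError("no classes present")
    for c, n_v in counts.items():
        if n_v <= 0:
            raise ValueError(f"class {c!r} has non-positive count {n_v}")
    n = sum(counts.values())
    k = len(counts)
    return ClassWeights({c: n / (k * n_v) for c, n_v in counts.items()}, n, k)


def weighted_gini(
    node_counts: Mapping[str, float],
    weights: ClassWeights | Mapping[str, float] | None = None,
) -> float:
    """G = 1 - sum_v w_v * p_v^2 with p_v the class proportions at the node."""
    counts = dict(node_counts)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("node has no samples")
    if weights is None:
        w = {c: 1.0 for c in counts}
    elif isinstance(weights, ClassWeights):
        w = weights.weights
    else:
        w = dict(weights)
    return 1.0 - sum(w.get(c, 1.0) * (cnt / total) ** 2 for c, cnt in counts.items())


DEFAULT_GRID = {
    "max_depth": [None, 10, 20],
    "max_features": ["sqrt", "log2"],
    "min_samples_leaf": [1, 5],
}


@dataclass
class RFConfig:
    n_trees: int = 1000
    grid: dict | None = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 10
    seed: int = 0
    impurity: str = "gini"  # "gini" (sklearn, class-weighted) or "literal"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.impurity not in ("gini", "literal"):
            raise ValueError(f"unknown impurity {self.impurity!r}")


def marker_matrix(
    X: ExpressionMatrix, marker_sets: Sequence[MarkerSet | Sequence[str]]
) -> ExpressionMatrix:
    """Restrict X to the union of the marker sets (the multiclass feature
    space); raises listing any marker genes absent from X."""
    union: list[str] = []
    seen = set()
    for ms in marker_sets:
        ids = ms.gene_ids if isinstance(ms, MarkerSet) else ms
        for g in ids:
            if g not in seen:
                seen.add(g)
                union.append(g)
    union.sort()
    present = set(X.gene_ids)
    missing = [g for g in union if g not in present]
    if missing:
        raise KeyError(f"marker genes absent from expression matrix: {missing[:20]}")
    return X.subset_genes(union)


def fit_rf(
    X: ExpressionMatrix | np.ndarray,
    labels: SubtypeLabelSet | np.ndarray,
    config: RFConfig | None = None,
    weights: ClassWeights | None = None,
):
    """Grow the class-weighted forest, with optional grid-searched
    hyperparameters (stratified ``cv_folds``-fold CV); reproducible under
    ``config.seed``."""
    config = config or RFConfig()
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    y = (
        labels.as_array(X.sample_ids)
        if isinstance(labels, SubtypeLabelSet) and isinstance(X, ExpressionMatrix)
        else np.asarray(labels if not isinstance(labels, SubtypeLabelSet) else labels.labels)
    )
    cw = None if weights is None else dict(weights.weights)
    if config.impurity == "literal":
        forest = LiteralGiniForest(
            n_trees=config.n_trees, class_weights=cw, seed=config.seed
        )
        forest.fit(Xv, y)
        return forest
    base = RandomForestClassifier(
        n_estimators=config.n_trees,
        class_weight=cw,
        random_state=config.seed,
        n_jobs=1,
    )
    if config.grid:
        folds = min(config.cv_folds, int(min(np.unique(y, return_counts=True)[1])))
        if folds < config.cv_folds:
            warnings.warn(
                f"cv_folds reduced to {folds} (smallest class size)", stacklevel=2
            )
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
        search = GridSearchCV(base, config.grid, cv=cv, scoring="accuracy", n_jobs=1)
        search.fit(Xv, y)
        return search.best_estimator_
    base.fit(Xv, y)
    return base


# ---------------------------------------------------------------------------
# Bundled forest with the literal weighted-Gini split criterion.
# Intended for small problems and for unit-testing the criterion itself.
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "proba")

    def __init__(self, proba=None):
        self.feature = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.proba = proba


class LiteralGiniTree:
    """CART-style binary tree whose split criterion is the literal
    class-weighted Gini G = 1 - sum_v w_v p_v^2."""

    def __init__(
        self,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        max_features: int | None = None,
        class_weights: Mapping[str, float] | None = None,
    ) -> None:
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.class_weights = class_weights

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        self.classes_ = np.array(sorted(set(y)))
        self._cls_index = {c: i for i, c in enumerate(self.classes_)}
        self._w = np.array(
            [
                1.0
                if self.class_weights is None
                else self.class_weights.get(c, 1.0)
                for c in self.classes_
            ]
        )
        yi = np.array([self._cls_index[c] for c in y])
        self.root_ = self._grow(np.asarray(X, float), yi, 0, rng)
        return self

    def _impurity(self, counts: np.ndarray) -> float:
        total = counts.sum()
        p = counts / total
        return 1.0 - float((self._w * p**2).sum())

    def _leaf(self, yi: np.ndarray) -> _Node:
        counts = np.bincount(yi, minlength=len(self.classes_)).astype(float)
        wc = counts * self._w
        return _Node(proba=wc / wc.sum())

    def _grow(self, X, yi, depth, rng) -> _Node:
        counts = np.bincount(yi, minlength=len(self.classes_)).astype(float)
        n = len(yi)
        if (
            n < 2 * self.min_samples_leaf
            or (self.max_depth is not None and depth >= self.max_depth)
            or (counts > 0).sum() <= 1
        ):
            return self._leaf(yi)
        d = X.shape[1]
        n_feat = self.max_features or d
        feats = rng.choice(d, size=min(n_feat, d), replace=False)
        parent_imp = self._impurity(counts)
        best = (parent_imp - 1e-12, -1, 0.0)  # (weighted child impurity, feat, thr)
        for f in feats:
            order = np.argsort(X[:, f], kind="stable")
            xs, ys = X[order, f], yi[order]
            left = np.zeros(len(self.classes_))
            right = counts.copy()
            for i in range(n - 1):
                left[ys[i]] += 1
                right[ys[i]] -= 1
                if xs[i + 1] == xs[i]:
                    continue
                nl = i + 1
                nr = n - nl
                if nl < self.min_samples_leaf or nr < self.min_samples_leaf:
                    continue
                imp = (nl / n) * self._impurity(left) + (nr / n) * self._impurity(
                    right
                )
                if imp < best[0]:
                    best = (imp, int(f), float((xs[i] + xs[i + 1]) / 2.0))
        if best[1] < 0:
            return self._leaf(yi)
        node = _Node()
        node.feature, node.threshold = best[1], best[2]
        mask = X[:, node.feature] <= node.threshold
        node.left = self._grow(X[mask], yi[mask], depth + 1, rng)
        node.right = self._grow(X[~mask], yi[~mask], depth + 1, rng)
        return node

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.empty((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            node = self.root_
            while node.proba is None:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.proba
        return out


class LiteralGiniForest:
    """Bootstrap ensemble of LiteralGiniTree; sklearn-like predict API."""

    def __init__(
        self,
        n_trees: int = 100,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        class_weights: Mapping[str, float] | None = None,
        seed: int = 0,
    ) -> None:
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.class_weights = class_weights
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.array(sorted(set(y)))
        n, d = X.shape
        max_features = max(1, int(np.sqrt(d)))
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = LiteralGiniTree(
                self.max_depth, self.min_samples_leaf, max_features, self.class_weights
            )
            tree.fit(X[idx], y[idx], rng)
            self.trees_.append(tree)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        acc = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees_:
            p = tree.predict_proba(X)
            cols = [list(tree.classes_).index(c) for c in self.classes_]
            acc += p[:, cols]
        return acc / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_auc: dict[str, float]
    weighted_auc: float
    confusion: pd.DataFrame
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    missing_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_weighted": self.precision,
            "recall_weighted": self.recall,
            "f1_weighted": self.f1,
            "per_class_auc": self.per_class_auc,
            "weighted_auc": self.weighted_auc,
            "missing_classes": self.missing_classes,
        }


def evaluate(
    classifier,
    X_test: ExpressionMatrix | np.ndarray,
    labels_test: SubtypeLabelSet | np.ndarray,
) -> EvalReport:
    """Accuracy, support-weighted precision/recall/F1, one-vs-rest ROC/AUC
    per class (trapezoidal), and the support-weighted mean AUC.

    A class absent from the test set has no defined ROC; it is reported in
    ``missing_classes`` and excluded from the weighted average (warning).
    """
    Xv = (
        X_test.values
        if isinstance(X_test, ExpressionMatrix)
        else np.asarray(X_test, float)
    )
    if isinstance(labels_test, SubtypeLabelSet):
        y = labels_test.as_array(
            X_test.sample_ids if isinstance(X_test, ExpressionMatrix) else None
        )
    else:
        y = np.asarray(labels_test)
    y_pred = classifier.predict(Xv)
    proba = classifier.predict_proba(Xv)
    classes = list(classifier.classes_)

    accuracy = float(accuracy_score(y, y_pred))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, y_pred, average="weighted", zero_division=0
    )
    conf = pd.DataFrame(
        confusion_matrix(y, y_pred, labels=classes), index=classes, columns=classes
    )

    per_class_auc: dict[str, float] = {}
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    missing: list[str] = []
    supports: dict[str, int] = {}
    for i, c in enumerate(classes):
        pos = y == c
        supports[c] = int(pos.sum())
        if supports[c] == 0 or supports[c] == len(y):
            missing.append(c)
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), proba[:, i])
        roc_curves[c] = (fpr, tpr)
        per_class_auc[c] = float(auc(fpr, tpr))
    if missing:
        warnings.warn(
            f"classes without a defined one-vs-rest ROC on this test set: "
            f"{missing}; excluded from the weighted AUC",
            stacklevel=2,
        )
    total_support = sum(supports[c] for c in per_class_auc)
    weighted_auc = (
        sum(per_class_auc[c] * supports[c] for c in per_class_auc) / total_support
        if total_support
        else float("nan")
    )
    return EvalReport(
        accuracy,
        float(precision),
        float(recall),
        float(f1),
        per_class_auc,
        float(weighted_auc),
        conf,
        roc_curves,
        missing,
    )
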