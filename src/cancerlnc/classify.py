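"""Training and evaluation of the balanced-resampling classifier ensemble.

Five algorithms are compared — random forest (RF), Gaussian naive Bayes
(NB), RBF-kernel SVM, logistic regression (LR) and k-nearest neighbors
(KNN) — each trained on the positives against every sampled balanced
negative set and scored by stratified ten-fold cross-validation, pooling
the out-of-fold scores of one run into a single ROC AUC.  Feature
importance uses extremely-randomized-trees impurity importance averaged
over the negative sets; unknown genes are scored by the mean predicted
positive-class probability of the per-set models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .features import FeatureTable

ALGORITHMS = ("rf", "nb", "svm", "lr", "knn")

#: Explicit hyperparameter defaults, serialized into every report.
DEFAULT_ALGORITHM_PARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 500},
    "nb": {},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "lr": {"C": 1.0, "max_iter": 2000},
    "knn": {"n_neighbors": 5},
}


def make_estimator(algorithm: str, seed: int = 0, params: Mapping | None = None):
    """Build one classifier.  Distance/margin-based models (SVM, LR, KNN)
    get column standardization fitted inside the training folds; tree and
    NB models consume raw features."""
    p = dict(DEFAULT_ALGORITHM_PARAMS.get(algorithm, {}))
    if params:
        p.update(params)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **p)
    if algorithm == "nb":
        return GaussianNB(**p)
    if algorithm == "svm":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", SVC(probability=True, random_state=seed, **p))]
        )
    if algorithm == "lr":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", LogisticRegression(random_state=seed, **p))]
        )
    if algorithm == "knn":
        return Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier(**p))])
    raise ValidationError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _derive_seed(seed: int, *indices: int) -> int:
    """Deterministic per-(stage, index) child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] % (2**31))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (trapezoidal; tied scores count 1/2,
    i.e. the Mann-Whitney convention)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValidationError("scores and labels differ in length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, scores))


def _xy(
    table: FeatureTable,
    positives: Iterable[str],
    negatives: Iterable[str],
    columns: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pos = sorted(positives)
    neg = sorted(negatives)
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValidationError(f"genes in both classes: {sorted(overlap)[:5]}")
    ids = pos + neg
    X = table.matrix(ids, columns)
    y = np.array([1] * len(pos) + [0] * len(neg))
    return X, y, ids


def _out_of_fold_scores(
    table: FeatureTable,
    positives: Iterable[str],
    negative_set: Iterable[str],
    algorithm: str,
    k: int,
    seed: int,
    columns: Sequence[str] | None,
    params: Mapping | None,
) -> tuple[np.ndarray, np.ndarray]:
    X, y, _ = _xy(table, positives, negative_set, columns)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if min(n_pos, n_neg) < k:
        raise ValidationError(
            f"smallest class ({min(n_pos, n_neg)}) is smaller than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(y.size)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = make_estimator(algorithm, seed=_derive_seed(seed, fold), params=params)
        est.fit(X[tr], y[tr])
        scores[te] = est.predict_proba(X[te])[:, 1]
    return scores, y


def crossval_auc(
    table: FeatureTable,
    positives: Iterable[str],
    negative_set: Iterable[str],
    algorithm: str = "rf",
    k: int = 10,
    seed: int = 0,
    columns: Sequence[str] | None = None,
    params: Mapping | None = None,
) -> float:
    """Pooled out-of-fold AUC of one stratified k-fold run on positives vs
    one balanced negative set."""
    scores, y = _out_of_fold_scores(
        table, positives, negative_set, algorithm, k, seed, columns, params
    )
    return roc_auc(scores, y)


def pooled_roc_points(
    table: FeatureTable,
    positives: Iterable[str],
    negative_sets: Sequence[Iterable[str]],
    algorithm: str = "rf",
    k: int = 10,
    seed: int = 0,
    params: Mapping | None = None,
) -> pd.DataFrame:
    """ROC curve (fpr, tpr) of the out-of-fold scores pooled across all
    negative sets, for plotting; seeds match :func:`evaluate_algorithms`."""
    all_scores, all_labels = [], []
    for i, neg in enumerate(negative_sets):
        scores, y = _out_of_fold_scores(
            table, positives, neg, algorithm, k, _derive_seed(seed, i),
            None, params,
        )
        all_scores.append(scores)
        all_labels.append(y)
    fpr, tpr, _ = roc_curve(np.concatenate(all_labels), np.concatenate(all_scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


@dataclass
class CVReport:
    """Cross-validation summary for one algorithm over the negative sets."""

    algorithm: str
    per_set_auc: list[float]
    seed: int
    fold_count: int
    params: dict = field(default_factory=dict)
    categories: tuple[str, ...] | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_set_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.per_set_auc, ddof=1)) if len(self.per_set_auc) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "per_set_auc": self.per_set_auc,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "seed": self.seed,
            "fold_count": self.fold_count,
            "params": self.params,
            "categories": list(self.categories) if self.categories else None,
        }


def evaluate_algorithms(
    table: FeatureTable,
    positives: Iterable[str],
    negative_sets: Sequence[Iterable[str]],
    algorithms: Sequence[str] = ALGORITHMS,
    k: int = 10,
    seed: int = 0,
    categories: Sequence[str] | None = None,
    params: Mapping[str, Mapping] | None = None,
) -> dict[str, CVReport]:
    """Per algorithm, one cross-validated AUC per negative set.

    `categories` restricts the feature matrix to a subset of feature
    categories (e.g. ``["epigenetic"]``), enabling the per-category and
    category-combination comparisons.
    """
    if not negative_sets:
        raise ValidationError("need at least one negative set")
    columns = None
    if categories is not None:
        columns = [c for cat in categories for c in table.columns_in(cat)]
        if not columns:
            raise ValidationError(f"no features in categories {categories}")
    out = {}
    for algo in algorithms:
        aucs = [
            crossval_auc(
                table, positives, neg, algorithm=algo, k=k,
                seed=_derive_seed(seed, i), columns=columns,
                params=(params or {}).get(algo),
            )
            for i, neg in enumerate(negative_sets)
        ]
        out[algo] = CVReport(
            algorithm=algo,
            per_set_auc=aucs,
            seed=seed,
            fold_count=k,
            params=dict(DEFAULT_ALGORITHM_PARAMS.get(algo, {}), **(params or {}).get(algo, {})),
            categories=tuple(categories) if categories else None,
        )
    return out


@dataclass
class ImportanceReport:
    """Features ranked by normalized impurity importance (sums to 1)."""

    table: pd.DataFrame  # columns: feature, importance, category (desc order)

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def top_category_counts(self, k: int) -> dict[str, int]:
        counts = self.top(k)["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in sorted(set(self.table["category"]))}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def feature_importance(
    table: FeatureTable,
    positives: Iterable[str],
    negative_sets: Sequence[Iterable[str]],
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceReport:
    """Extremely-randomized-trees impurity importance, averaged over the
    balanced negative sets and normalized to sum to one."""
    if not negative_sets:
        raise ValidationError("need at least one negative set")
    total = np.zeros(len(table.feature_names))
    for i, neg in enumerate(negative_sets):
        X, y, _ = _xy(table, positives, neg, None)
        est = ExtraTreesClassifier(
            n_estimators=n_trees, random_state=_derive_seed(seed, i)
        )
        est.fit(X, y)
        total += est.feature_importances_
    total /= total.sum()
    df = pd.DataFrame(
        {
            "feature": table.feature_names,
            "importance": total,
            "category": [table.categories[c] for c in table.feature_names],
        }
    ).sort_values("importance", ascending=False, kind="mergesort")
    return ImportanceReport(df.reset_index(drop=True))


class NegativeResamplingEnsemble(BaseEstimator, ClassifierMixin):
    """Balanced ensemble over resampled negative sets (scikit-learn API).

    ``fit(X, y)`` takes y=1 for curated positives and y=0 for the whole
    negative pool; `n_sets` balanced subsets of `set_size` negatives are
    sampled without replacement and one base classifier is fitted per
    subset on positives vs that subset.  ``predict_proba`` averages the
    member probabilities, which is also the candidate-calling score.

    Parameters
    ----------
    algorithm : str
        One of ``rf, nb, svm, lr, knn``.
    n_sets : int
        Number of resampled negative sets / ensemble members.
    set_size : int or None
        Negatives per set; ``None`` matches the number of positives,
        capped at the pool size.
    params : dict or None
        Hyperparameter overrides for the base classifier.
    random_state : int
        Seed for both the resampling and the base classifiers.
    """

    def __init__(
        self,
        algorithm: str = "rf",
        n_sets: int = 100,
        set_size: int | None = 150,
        params: Mapping | None = None,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.n_sets = n_sets
        self.set_size = set_size
        self.params = params
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValidationError("y must contain both classes coded 0/1")
        pos_idx = np.flatnonzero(y == 1)
        pool_idx = np.flatnonzero(y == 0)
        size = self.set_size
        if size is None:
            size = min(len(pos_idx), len(pool_idx))
        if size > len(pool_idx):
            raise ValidationError(
                f"set_size {size} exceeds negative pool size {len(pool_idx)}"
            )
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        self.sets_idx_ = []
        for i in range(self.n_sets):
            subset = np.sort(rng.choice(pool_idx, size=size, replace=False))
            idx = np.concatenate([pos_idx, subset])
            est = make_estimator(
                self.algorithm, seed=_derive_seed(self.random_state, i),
                params=self.params,
            )
            est.fit(X[idx], y[idx])
            self.estimators_.append(est)
            self.sets_idx_.append(subset)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        probs = np.mean([e.predict_proba(X)[:, 1] for e in self.estimators_], axis=0)
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass(frozen=True)
class PredictionResult:
    gene_id: str
    mean_probability: float
    n_models: int
    is_candidate: bool


def predict_candidates(
    table: FeatureTable,
    positives: Iterable[str],
    negative_sets: Sequence[Iterable[str]],
    unknown_ids: Sequence[str],
    threshold: float = 0.5,
    mode: str = "ensemble",
    algorithm: str = "rf",
    seed: int = 0,
    k: int = 10,
    params: Mapping | None = None,
) -> list[PredictionResult]:
    """Score unknown genes against the trained per-set models.

    ``ensemble`` mode averages the positive-class probability over one
    model per negative set; ``single_best`` retrains only on the negative
    set with the highest cross-validated AUC.  A gene is a candidate when
    its (mean) probability exceeds `threshold`.
    """
    if mode not in ("ensemble", "single_best"):
        raise ValidationError(f"unknown prediction mode {mode!r}")
    unknown_ids = list(unknown_ids)
    if not unknown_ids:
        return []
    positives = sorted(set(positives))
    forbidden = set(positives).union(*[set(s) for s in negative_sets])
    clash = [u for u in unknown_ids if u in forbidden]
    if clash:
        raise ValidationError(
            f"unknown genes overlap the training sets: {clash[:5]}"
        )
    X_unknown = table.matrix(unknown_ids)

    if mode == "single_best":
        aucs = [
            crossval_auc(table, positives, neg, algorithm=algorithm, k=k,
                         seed=_derive_seed(seed, i), params=params)
            for i, neg in enumerate(negative_sets)
        ]
        chosen = [negative_sets[int(np.argmax(aucs))]]
    else:
        chosen = list(negative_sets)

    probs = np.zeros(len(unknown_ids))
    for i, neg in enumerate(chosen):
        X, y, _ = _xy(table, positives, neg, None)
        est = make_estimator(algorithm, seed=_derive_seed(seed, 7919, i), params=params)
        est.fit(X, y)
        probs += est.predict_proba(X_unknown)[:, 1]
    probs /= len(chosen)

    return [
        PredictionResult(g, float(p), len(chosen), bool(p > threshold))
        for g, p in zip(unknown_ids, probs)
    ]


def predictions_to_dataframe(results: Sequence[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_probability": r.mean_probability,
                "n_models": r.n_models,
                "is_candidate": r.is_candidate,
            }
            for r in results
        ],
        columns=["gene_id", "mean_probability", "n_models", "is_candidate"],
    )
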