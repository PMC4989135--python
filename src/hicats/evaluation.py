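"""Subset fitness: cross-validated classification accuracy vs subset size.

A gene subset is scored as

    fitness = w1 * A + w2 * (n - D) / n

where ``A`` is the cross-validated accuracy of a classifier restricted to
the subset's columns (a fraction in [0, 1]), ``D`` the subset size, ``n``
the total gene count, and ``w2 = 1 - w1``. High ``w1`` (default 0.8)
prioritises accuracy; the size term rewards small subsets.

Accuracy is computed by an explicit fold loop: features are standardised
with train-fold statistics only (no leakage into held-out samples), the
classifier is refit per fold, and held-out predictions are pooled. The
evaluator memoises by exact bit pattern, counts classifier-fit passes,
and keeps an elitist archive of the best country it has ever scored —
fitness calls dominate the cost of the surrounding search, so all three
matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .core import Country, GeneDataset

__all__ = [
    "FitnessWeights",
    "SubsetEvaluator",
    "make_classifier",
    "loocv_accuracy",
    "cv_accuracy",
    "subset_fitness",
    "evaluate_population",
]

CLASSIFIERS = ("svm", "svm-ovr", "knn", "centroid")


@dataclass(frozen=True)
class FitnessWeights:
    """Accuracy weight ``w1``; the size weight ``w2`` is always ``1 - w1``."""

    w1: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError(f"w1 must be in [0, 1], got {self.w1}")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1


def make_classifier(spec: str):
    """Instantiate a classifier family by name.

    ``svm`` is the default linear support-vector machine (libsvm, pairwise
    multiclass); ``svm-ovr`` the one-vs-rest linear variant; ``knn`` a
    3-nearest-neighbour voter; ``centroid`` nearest class centroid.
    """
    if spec == "svm":
        return SVC(kernel="linear")
    if spec == "svm-ovr":
        return LinearSVC()
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if spec == "centroid":
        return NearestCentroid()
    raise ValueError(f"unknown classifier {spec!r}; choose from {CLASSIFIERS}")


def _make_folds(labels: np.ndarray, cv: str | int) -> list[tuple[np.ndarray, np.ndarray]]:
    n = labels.shape[0]
    if cv == "loocv":
        idx = np.arange(n)
        return [(np.delete(idx, i), idx[i : i + 1]) for i in range(n)]
    k = int(cv)
    if k < 2:
        raise ValueError(f"k-fold cross-validation needs k >= 2, got {k}")
    _, counts = np.unique(labels, return_counts=True)
    k = min(k, int(counts.min()))
    if k < 2:
        # a singleton class cannot be stratified into folds; fall back to LOOCV
        return _make_folds(labels, "loocv")
    skf = StratifiedKFold(n_splits=k, shuffle=False)
    return [(tr, te) for tr, te in skf.split(np.zeros((n, 1)), labels)]


def _pooled_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    classifier,
) -> float:
    correct = 0
    for train, test in folds:
        Xtr, Xte = X[train], X[test]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0.0] = 1.0
        ytr = y[train]
        if np.unique(ytr).shape[0] < 2:
            # degenerate training fold: predict its only class
            correct += int(np.sum(y[test] == ytr[0]))
            continue
        clf = clone(classifier)
        clf.fit((Xtr - mu) / sd, ytr)
        correct += int(np.sum(clf.predict((Xte - mu) / sd) == y[test]))
    return correct / y.shape[0]


class SubsetEvaluator:
    """Maps gene subsets to (accuracy, fitness) with per-run memoisation.

    Parameters
    ----------
    dataset
        Expression data with labels.
    classifier
        Name from :data:`CLASSIFIERS` or a scikit-learn estimator instance.
    cv
        ``"loocv"`` (default, the evaluation scheme of the method) or an
        integer ``k`` for stratified k-fold (faster; folds are clamped to
        the smallest class size).
    """

    def __init__(self, dataset: GeneDataset, classifier="svm", cv: str | int = "loocv"):
        self.dataset = dataset
        self.classifier = (
            make_classifier(classifier) if isinstance(classifier, str) else classifier
        )
        self.cv = cv
        self._folds = _make_folds(dataset.labels, cv)
        self._single_class = dataset.classes.shape[0] < 2
        self.cache: dict[bytes, tuple[float, float]] = {}
        self.n_fits = 0
        self.best: Country | None = None

    def accuracy_of_columns(self, cols: np.ndarray) -> float:
        """Cross-validated accuracy on 0-based column indices (uncached)."""
        if self._single_class:
            return 1.0
        X = np.ascontiguousarray(self.dataset.matrix[:, cols])
        self.n_fits += 1
        return _pooled_accuracy(X, self.dataset.labels, self._folds, self.classifier)

    def evaluate(self, country: Country, weights: FitnessWeights) -> Country:
        """Set ``fitness`` and ``accuracy`` on the country, via the cache."""
        d = country.n_selected
        if d == 0:
            raise ValueError("cannot evaluate an empty country; repair it first")
        key = country.key()
        hit = self.cache.get(key)
        if hit is None:
            acc = self.accuracy_of_columns(np.flatnonzero(country.bits))
            n = self.dataset.n
            fit = weights.w1 * acc + weights.w2 * (n - d) / n
            self.cache[key] = hit = (acc, fit)
        country.accuracy, country.fitness = hit
        if self.best is None or country.fitness > self.best.fitness:
            self.best = country.copy()
        return country


def cv_accuracy(
    dataset: GeneDataset,
    subset,
    classifier_spec: str = "svm",
    cv: str | int = "loocv",
) -> float:
    """Cross-validated accuracy of a classifier on 1-based gene positions."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    for p in subset:
        if not 1 <= p <= dataset.n:
            raise ValueError(f"gene position {p} outside 1..{dataset.n}")
    ev = SubsetEvaluator(dataset, classifier_spec, cv)
    return ev.accuracy_of_columns(np.asarray(subset, dtype=int) - 1)


def loocv_accuracy(dataset: GeneDataset, subset, classifier_spec: str = "svm") -> float:
    """Leave-one-out accuracy: each sample predicted by a model trained on the rest."""
    return cv_accuracy(dataset, subset, classifier_spec, "loocv")


def subset_fitness(
    country: Country, evaluator: SubsetEvaluator, weights: FitnessWeights
) -> float:
    """Evaluate one country and return its fitness."""
    return evaluator.evaluate(country, weights).fitness


def evaluate_population(
    countries: list[Country], evaluator: SubsetEvaluator, weights: FitnessWeights
) -> list[Country]:
    """Evaluate every country in place; duplicates cost one classifier pass."""
    for c in countries:
        evaluator.evaluate(c, weights)
    return countries
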