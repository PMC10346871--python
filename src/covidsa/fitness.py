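"""Wrapper objective: classifier error on the selected columns plus a
subset-size penalty.

fitness = a * epsilon + (1 - a) * SSize / TSize

where epsilon is the misclassification rate of a classifier trained on the
selected feature columns, SSize the number of selected features and TSize
the total feature count.  The native classifier is a fully deterministic
k-nearest-neighbours vote; any learner honouring the fit/predict adapter
contract can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.spatial.distance import cdist

from .data import FeatureDataset, stratified_split_indices

__all__ = [
    "ClassifierSpec",
    "FitnessSpec",
    "FitnessBreakdown",
    "KNNClassifier",
    "knn_predict",
    "classifier_error",
    "fitness_eval",
    "WrapperFitness",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "minkowski": "minkowski"}


class ClassifierAdapter(Protocol):
    """Contract any external classifier must honour to replace the native KNN."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> object: ...

    def predict(self, x: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier backs the wrapper objective.

    ``kind="knn-native"`` uses the in-package KNN (default k=5, Euclidean);
    ``kind="external-adapter"`` wraps any fit/predict object produced by
    ``adapter_factory``.  ``p`` is the Minkowski order and is only consulted
    for ``metric="minkowski"``.
    """

    kind: str = "knn-native"
    k: int = 5
    metric: str = "euclidean"
    p: float = 3.0
    adapter_factory: Callable[[], ClassifierAdapter] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("knn-native", "external-adapter"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.kind == "external-adapter" and self.adapter_factory is None:
            raise ValueError("external-adapter kind requires adapter_factory")

    def make(self) -> "KNNClassifier | ClassifierAdapter":
        if self.kind == "knn-native":
            return KNNClassifier(k=self.k, metric=self.metric, p=self.p)
        return self.adapter_factory()


@dataclass(frozen=True)
class FitnessSpec:
    """Wrapper-objective configuration.

    ``a`` weights the error term against the subset-size penalty; the
    default 0.99 keeps fitness values comparable across evaluations.
    ``a_mode="random"`` instead draws a fresh a ~ U[0,1] per evaluation.
    ``protocol`` selects which partition supplies epsilon: the published
    test split (``holdout-test``), a stratified validation split carved out
    of the training rows (``validation-split``, leakage-free), or stratified
    ``k-fold`` cross-validation over the training rows.
    """

    a: float = 0.99
    a_mode: str = "fixed"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    protocol: str = "holdout-test"
    cache_enabled: bool = True
    val_fraction: float = 0.2
    val_seed: int = 0
    n_folds: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must lie in [0, 1], got {self.a}")
        if self.a_mode not in ("fixed", "random"):
            raise ValueError(f"unknown a_mode {self.a_mode!r}")
        if self.protocol not in ("holdout-test", "validation-split", "k-fold"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class FitnessBreakdown:
    """One evaluated objective value with its components."""

    fitness: float
    epsilon: float
    s_size: int
    t_size: int
    a: float


class KNNClassifier:
    """Deterministic k-nearest-neighbours majority vote.

    Tie handling is fully specified so repeated runs are bit-identical:
    neighbour-distance ties are broken by training-row order (stable sort),
    vote ties by the smaller mean neighbour distance, then by the smaller
    label index.
    """

    def __init__(self, k: int = 5, metric: str = "euclidean", p: float = 3.0) -> None:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if metric not in _METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        self.k = k
        self.metric = metric
        self.p = p
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("training matrix must be 2-D and non-empty")
        if y.shape != (x.shape[0],):
            raise ValueError("labels must match the number of training rows")
        if self.k > x.shape[0]:
            raise ValueError(f"k={self.k} exceeds {x.shape[0]} training rows")
        self._x, self._y = x, y
        return self

    def _distances(self, queries: np.ndarray) -> np.ndarray:
        kw = {"p": self.p} if self.metric == "minkowski" else {}
        return cdist(queries, self._x, metric=_METRICS[self.metric], **kw)

    def _k_nearest(self, d: np.ndarray) -> np.ndarray:
        """Indices of the k nearest training rows per query row.

        Distance ties at the k-th position are broken by training-row order.
        Uses an O(n) partition; rows with a boundary tie fall back to an
        explicit row-order resolution, so the selected set is exact.
        """
        k, n = self.k, d.shape[1]
        if k == n:
            return np.broadcast_to(np.arange(n), d.shape).copy()
        part = np.argpartition(d, k - 1, axis=1)[:, :k]
        vmax = np.take_along_axis(d, part, axis=1).max(axis=1)
        tied = (d <= vmax[:, None]).sum(axis=1) > k
        for i in np.flatnonzero(tied):
            strict = np.flatnonzero(d[i] < vmax[i])
            at_boundary = np.flatnonzero(d[i] == vmax[i])
            part[i] = np.concatenate([strict, at_boundary[: k - strict.size]])
        return part

    def predict(self, queries: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("classifier is not fitted")
        queries = np.asarray(queries, dtype=float)
        if queries.ndim == 1:
            queries = queries[None, :]
        if queries.shape[1] != self._x.shape[1]:
            raise ValueError(
                f"query dimension {queries.shape[1]} != training dimension {self._x.shape[1]}"
            )
        d = self._distances(queries)
        nbr_idx = self._k_nearest(d)
        nbr_labels = self._y[nbr_idx]                     # (q, k)
        nbr_dist = np.take_along_axis(d, nbr_idx, axis=1)  # (q, k)

        n_classes = int(self._y.max()) + 1
        counts = (nbr_labels[:, :, None] == np.arange(n_classes)).sum(axis=1)
        top = counts.max(axis=1)
        pred = counts.argmax(axis=1)  # argmax already prefers the lower label
        tied = (counts == top[:, None]).sum(axis=1) > 1
        for i in np.flatnonzero(tied):
            cands = np.flatnonzero(counts[i] == top[i])
            means = np.array(
                [nbr_dist[i][nbr_labels[i] == c].mean() for c in cands]
            )
            # smallest mean distance wins; argmin prefers the lower label on ties
            pred[i] = cands[np.argmin(means)]
        return pred.astype(np.int64)


def knn_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    query: np.ndarray,
    k: int,
    metric: str = "euclidean",
    p: float = 3.0,
):
    """Classify one query vector by majority vote among its k nearest rows."""
    clf = KNNClassifier(k=k, metric=metric, p=p).fit(train_x, train_y)
    return int(clf.predict(np.asarray(query, dtype=float)[None, :])[0])


def _error(clf, train_x, train_y, eval_x, eval_y) -> float:
    clf.fit(train_x, train_y)
    return float(np.mean(clf.predict(eval_x) != eval_y))


def classifier_error(
    mask: np.ndarray,
    dataset: FeatureDataset,
    spec: ClassifierSpec | None = None,
    protocol: str = "holdout-test",
    val_fraction: float = 0.2,
    val_seed: int = 0,
    n_folds: int = 5,
) -> float:
    """Misclassification fraction of the classifier on the selected columns.

    The classifier is trained on the training partition restricted to the
    mask's set columns and evaluated on the partition the protocol names.
    """
    spec = spec or ClassifierSpec()
    cols = np.flatnonzero(np.asarray(mask, dtype=np.uint8))
    if cols.size == 0:
        raise ValueError("mask selects no features (repair happens upstream)")
    tx, ty = dataset.train_x[:, cols], dataset.train_y
    if protocol == "holdout-test":
        return _error(spec.make(), tx, ty, dataset.test_x[:, cols], dataset.test_y)
    if protocol == "validation-split":
        rng = np.random.default_rng(val_seed)
        tr, va = stratified_split_indices(ty, 1.0 - val_fraction, rng)
        return _error(spec.make(), tx[tr], ty[tr], tx[va], ty[va])
    if protocol == "k-fold":
        rng = np.random.default_rng(val_seed)
        folds = _stratified_folds(ty, n_folds, rng)
        errs = []
        for va in folds:
            tr = np.setdiff1d(np.arange(ty.size), va)
            errs.append(_error(spec.make(), tx[tr], ty[tr], tx[va], ty[va]))
        return float(np.mean(errs))
    raise ValueError(f"unknown protocol {protocol!r}")


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def fitness_eval(
    mask: np.ndarray,
    dataset: FeatureDataset,
    spec: FitnessSpec | None = None,
    rng: np.random.Generator | None = None,
) -> FitnessBreakdown:
    """Evaluate the wrapper objective for one mask (uncached convenience)."""
    spec = spec or FitnessSpec()
    eps = classifier_error(
        mask,
        dataset,
        spec.classifier,
        protocol=spec.protocol,
        val_fraction=spec.val_fraction,
        val_seed=spec.val_seed,
        n_folds=spec.n_folds,
    )
    return _combine(mask, dataset.n_features, eps, spec, rng)


def _combine(mask, t_size, eps, spec, rng) -> FitnessBreakdown:
    if spec.a_mode == "random":
        if rng is None:
            raise ValueError("random a_mode requires an rng")
        a = float(rng.random())
    else:
        a = spec.a
    s_size = int(np.asarray(mask, dtype=np.uint8).sum())
    fitness = a * eps + (1.0 - a) * s_size / t_size
    return FitnessBreakdown(fitness=float(fitness), epsilon=float(eps),
                            s_size=s_size, t_size=int(t_size), a=a)


class WrapperFitness:
    """Callable wrapper objective with a transparent per-mask error cache.

    The cache stores only the classifier error keyed by the mask bits, so
    enabling it never changes a returned value — only how often the
    classifier actually runs (``n_classifier_calls`` vs ``n_evals``).
    """

    def __init__(
        self,
        dataset: FeatureDataset,
        spec: FitnessSpec | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.dataset = dataset
        self.spec = spec or FitnessSpec()
        self._rng = rng if rng is not None else np.random.default_rng(0)
        self._cache: dict[bytes, float] = {}
        self.n_evals = 0
        self.n_classifier_calls = 0

    def __call__(self, mask: np.ndarray) -> FitnessBreakdown:
        mask = np.ascontiguousarray(mask, dtype=np.uint8)
        self.n_evals += 1
        key = mask.tobytes()
        if self.spec.cache_enabled and key in self._cache:
            eps = self._cache[key]
        else:
            eps = classifier_error(
                mask,
                self.dataset,
                self.spec.classifier,
                protocol=self.spec.protocol,
                val_fraction=self.spec.val_fraction,
                val_seed=self.spec.val_seed,
                n_folds=self.spec.n_folds,
            )
            self.n_classifier_calls += 1
            if self.spec.cache_enabled:
                self._cache[key] = eps
        return _combine(mask, self.dataset.n_features, eps, self.spec, self._rng)
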