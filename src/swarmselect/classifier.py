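"""k-nearest-neighbour classification and the cross-validated accuracy fitness.

The fitness a candidate gene subset receives is the mean accuracy (as a
percentage) of a k-NN classifier over seeded stratified folds, using only
the masked genes as features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_data import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class FitnessResult:
    """Per-fold and mean k-NN accuracy, both on the 0-100 percentage scale."""

    fold_accuracies: list[float]
    mean_accuracy: float
    c_total: int  # correctly classified test samples, summed over folds
    t_total: int  # total test samples over folds


def _squared_distances(test_X: np.ndarray, train_X: np.ndarray) -> np.ndarray:
    """(n_test, n_train) squared Euclidean distances."""
    diff = test_X[:, None, :] - train_X[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _knn_from_sqdist(
    d2: np.ndarray, train_y_int: np.ndarray, k: int, n_classes: int
) -> np.ndarray:
    """Predicted class ints from a squared-distance matrix.

    Distance ties break toward the lower training-sample index (stable
    argsort); vote ties toward the lower class index (class 1 first).
    """
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    neighbour_classes = train_y_int[order]
    votes = np.zeros((d2.shape[0], n_classes), dtype=int)
    for c in range(n_classes):
        votes[:, c] = (neighbour_classes == c).sum(axis=1)
    return votes.argmax(axis=1)  # argmax takes the first maximum: class-1 wins ties


def knn_predict(
    train_X: np.ndarray,
    train_y,
    test_X: np.ndarray,
    k: int,
    metric: str = "euclidean",
    classes=None,
) -> list:
    """Majority label among the k nearest training samples per test sample.

    ``classes`` fixes the tie-break preference order; default is order of
    first appearance in ``train_y``.
    """
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}; only 'euclidean'")
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = list(train_y)
    if train_X.ndim != 2 or test_X.ndim != 2:
        raise ValueError("train_X and test_X must be 2-D (samples x features)")
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if train_X.shape[1] == 0:
        raise ValueError("zero features")
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError(
            f"feature mismatch: train has {train_X.shape[1]}, test has {test_X.shape[1]}"
        )
    if len(train_y) != train_X.shape[0]:
        raise ValueError("train_y length must match train_X rows")
    if not 1 <= k <= train_X.shape[0]:
        raise ValueError(f"k must be in [1, {train_X.shape[0]}], got {k}")

    if classes is None:
        classes = []
        for l in train_y:
            if l not in classes:
                classes.append(l)
    else:
        classes = list(classes)
    class_to_int = {c: i for i, c in enumerate(classes)}
    y_int = np.asarray([class_to_int[l] for l in train_y], dtype=int)

    d2 = _squared_distances(test_X, train_X)
    pred_int = _knn_from_sqdist(d2, y_int, k, len(classes))
    return [classes[i] for i in pred_int]


def accuracy(predicted, true) -> float:
    """Percentage of correct predictions: (c / t) * 100."""
    predicted = list(predicted)
    true = list(true)
    if len(predicted) != len(true):
        raise ValueError("label vectors differ in length")
    if not true:
        raise ValueError("empty label vectors")
    c = sum(1 for p, t in zip(predicted, true) if p == t)
    return 100.0 * c / len(true)


def stratified_folds(
    labels, class_names, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified partition: list of test-index arrays, one per fold.

    Samples are shuffled once; within each class they are dealt round-robin
    to folds, so fold class proportions match the dataset's.
    """
    labels = list(labels)
    n = len(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = {c: labels.count(c) for c in class_names}
    smallest = min(counts.values())
    if n_folds > smallest:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class size {smallest}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in class_names:
        members = [int(i) for i in perm if labels[i] == cls]
        for pos, idx in enumerate(members):
            folds[pos % n_folds].append(idx)
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def cv_fitness(
    ds: ExpressionDataset,
    gene_mask,
    k: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    scale: str | None = None,
) -> FitnessResult:
    """Mean stratified-CV k-NN accuracy on the masked genes only.

    An empty mask short-circuits to fitness 0 without running CV.
    ``scale="zscore"`` standardizes each gene with training-fold statistics.
    """
    mask = np.asarray(sorted(int(g) for g in np.asarray(gene_mask).ravel()), dtype=int)
    if mask.size == 0:
        return FitnessResult(fold_accuracies=[], mean_accuracy=0.0, c_total=0, t_total=0)
    if scale not in (None, "zscore"):
        raise ValueError(f"scale must be None or 'zscore', got {scale!r}")

    folds = stratified_folds(ds.labels, ds.class_names, n_folds, seed)
    X = ds.matrix[mask, :].T  # samples x features
    y = ds.labels
    class_names = list(ds.class_names)
    class_to_int = {c: i for i, c in enumerate(class_names)}
    y_int = np.asarray([class_to_int[l] for l in y], dtype=int)

    fold_accs: list[float] = []
    c_total = 0
    t_total = 0
    all_idx = np.arange(ds.n_samples)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr, Xte = X[train_idx], X[test_idx]
        if scale == "zscore":
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        d2 = _squared_distances(Xte, Xtr)
        pred = _knn_from_sqdist(d2, y_int[train_idx], k, len(class_names))
        correct = int((pred == y_int[test_idx]).sum())
        c_total += correct
        t_total += len(test_idx)
        fold_accs.append(100.0 * correct / len(test_idx))
    return FitnessResult(
        fold_accuracies=fold_accs,
        mean_accuracy=float(np.mean(fold_accs)),
        c_total=c_total,
        t_total=t_total,
    )


class CVFitnessEvaluator:
    """Caching fitness function over gene masks of one candidate gene set.

    Folds are fixed at construction (seeded), results are cached by the
    decoded mask bit-pattern, and per-feature fold distance contributions
    are precomputed when small enough, making repeated mask evaluations
    cheap.  Produces results identical to :func:`cv_fitness` with the same
    (dataset, k, n_folds, seed).
    """

    _PRECOMPUTE_BUDGET = 2e8  # bytes of per-feature distance tensors

    def __init__(
        self,
        ds: ExpressionDataset,
        k: int = 5,
        n_folds: int = 5,
        seed: int = 0,
    ) -> None:
        self.ds = ds
        self.k = k
        self.n_folds = n_folds
        self.seed = seed
        self.evaluations = 0
        self._cache: dict[bytes, FitnessResult] = {}

        self._folds = stratified_folds(ds.labels, ds.class_names, n_folds, seed)
        class_to_int = {c: i for i, c in enumerate(ds.class_names)}
        self._y_int = np.asarray([class_to_int[l] for l in ds.labels], dtype=int)
        self._n_classes = len(ds.class_names)

        all_idx = np.arange(ds.n_samples)
        self._splits = [
            (np.setdiff1d(all_idx, test_idx), test_idx) for test_idx in self._folds
        ]
        n_feat = ds.n_genes
        bytes_needed = sum(
            8 * n_feat * len(te) * len(tr) for tr, te in self._splits
        )
        self._per_feature_d2: list[np.ndarray] | None = None
        if bytes_needed <= self._PRECOMPUTE_BUDGET:
            X = ds.matrix  # genes x samples
            self._per_feature_d2 = [
                (X[:, te][:, :, None] - X[:, tr][:, None, :]) ** 2
                for tr, te in self._splits
            ]

    def fitness_result(self, gene_mask) -> FitnessResult:
        mask = np.asarray(
            sorted(int(g) for g in np.asarray(gene_mask).ravel()), dtype=int
        )
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.evaluations += 1
        if mask.size == 0:
            result = FitnessResult([], 0.0, 0, 0)
        elif self._per_feature_d2 is not None:
            fold_accs: list[float] = []
            c_total = 0
            t_total = 0
            for (train_idx, test_idx), D in zip(self._splits, self._per_feature_d2):
                d2 = D[mask].sum(axis=0)
                pred = _knn_from_sqdist(d2, self._y_int[train_idx], self.k, self._n_classes)
                correct = int((pred == self._y_int[test_idx]).sum())
                c_total += correct
                t_total += len(test_idx)
                fold_accs.append(100.0 * correct / len(test_idx))
            result = FitnessResult(
                fold_accs, float(np.mean(fold_accs)), c_total, t_total
            )
        else:
            result = cv_fitness(self.ds, mask, self.k, self.n_folds, self.seed)
        self._cache[key] = result
        return result

    def __call__(self, gene_mask) -> float:
        return self.fitness_result(gene_mask).mean_accuracy
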