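"""Peak-cluster classification: GA, SNN and QC models with validation.

Three model families operate on the samples x peak-clusters matrix:

* **QC** (quick classifier): univariate p-value-weighted voting.  Clusters
  are ranked by their Wilcoxon p-value; each of the best ``top_k`` votes
  for the class whose training centroid is nearer, with weight -log10(p).
* **SNN** (supervised neural network): a learning-vector-quantization
  scheme (LVQ1).  Per-class prototypes are initialised by class-stratified
  k-means on standardized intensities and updated by attracting the
  winning prototype towards same-class samples and repelling it from
  other-class samples, with a linearly decaying learning rate.
* **GA** (genetic algorithm): feature-subset selection.  A chromosome is a
  cluster subset; its fitness is the internal stratified 3-fold
  cross-validated accuracy of a nearest-centroid classifier on that
  subset; tournament selection, uniform crossover and per-gene mutation
  evolve the population.

Model reliability is reported as leave-one-out cross-validation % (the
model is retrained from scratch on each fold, so feature selection cannot
leak), recognition capability % (training samples correctly classified by
the final model) and per-class correct-classification rates.  All
percentages and predictions are deterministic given seed and config; ties
are broken towards the first class of the label encoding (allergy first).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from .peaks import PeakClusterMatrix
from .stats import wilcoxon_rank_sum

_EPS = 1e-12


def _class_order(y: np.ndarray, classes: list[str] | None) -> list[str]:
    if classes is not None:
        return list(classes)
    seen = list(dict.fromkeys(y.tolist()))
    if "allergy" in seen:  # documented tie-break order: allergy first
        seen.remove("allergy")
        seen.insert(0, "allergy")
    return seen


@dataclass
class _Scaler:
    """Per-feature z-score parameters fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < _EPS] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def _check_finite(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the feature matrix")


@dataclass
class Prediction:
    """A class call with normalized per-class scores."""

    label: str
    scores: dict[str, float]
    low_confidence: bool


class ClassifierModel:
    """Shared prediction interface of the three model kinds."""

    kind: str
    classes: list[str]
    selected: np.ndarray  # indices of the clusters the model uses
    n_features: int

    def _score_matrix(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) scores, each row summing to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} cluster intensities, "
                f"got {X.shape[1]}"
            )
        _check_finite(X)
        scores = self._score_matrix(X)
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        # argmax returns the first maximum: ties go to the first-listed class
        return np.array([self.classes[i] for i in np.argmax(scores, axis=1)])


def classify(model: ClassifierModel, sample_vector) -> Prediction:
    """Classify one sample; flags predictions with a score gap < 0.1."""
    scores = model.predict_scores(np.asarray(sample_vector, dtype=float))[0]
    order = np.sort(scores)[::-1]
    gap = float(order[0] - order[1]) if order.size > 1 else 1.0
    label = model.classes[int(np.argmax(scores))]
    return Prediction(
        label=label,
        scores={c: float(s) for c, s in zip(model.classes, scores)},
        low_confidence=gap < 0.1,
    )


def _inverse_distance_scores(dist: np.ndarray) -> np.ndarray:
    return 1.0 / (dist + _EPS)


# ---------------------------------------------------------------------------
# QC — quick classifier


@dataclass
class QCConfig:
    top_k: int = 10


class QCModel(ClassifierModel):
    kind = "QC"

    def __init__(self, classes, selected, centroids, weights, n_features):
        self.classes = classes
        self.selected = np.asarray(selected)
        self.centroids = np.asarray(centroids)  # (n_classes, k)
        self.weights = np.asarray(weights)  # (k,)
        self.n_features = n_features

    def _score_matrix(self, X: np.ndarray) -> np.ndarray:
        sub = X[:, self.selected]  # (n, k)
        dist = np.abs(sub[:, None, :] - self.centroids[None, :, :])
        # each cluster votes for its nearer class centroid; ties -> class 0
        votes = np.argmin(dist, axis=1)  # (n, k)
        total = self.weights.sum()
        if total <= 0:
            return np.full((X.shape[0], len(self.classes)), 1.0)
        scores = np.zeros((X.shape[0], len(self.classes)))
        for j in range(len(self.classes)):
            scores[:, j] = ((votes == j) * self.weights).sum(axis=1) / total
        scores[scores.sum(axis=1) == 0] = 1.0  # all-zero guard
        return scores


def train_qc(
    X: np.ndarray,
    y,
    config: QCConfig | None = None,
    classes: list[str] | None = None,
) -> QCModel:
    """Rank clusters by Wilcoxon p, keep the best, vote by nearer centroid."""
    config = config or QCConfig()
    if config.top_k < 1:
        raise ValueError("top_k must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_finite(X)
    order = _class_order(y, classes)
    _require_min_per_class(y, order, 2)
    pos = y == order[0]
    pvals = np.array(
        [wilcoxon_rank_sum(X[pos, j], X[~pos, j]) for j in range(X.shape[1])]
    )
    k = min(config.top_k, X.shape[1])
    selected = np.sort(np.argsort(pvals, kind="stable")[:k])
    weights = -np.log10(np.maximum(pvals[selected], 1e-300))
    centroids = np.vstack(
        [X[np.ix_(y == c, selected)].mean(axis=0) for c in order]
    )
    return QCModel(order, selected, centroids, weights, X.shape[1])


# ---------------------------------------------------------------------------
# SNN — supervised neural network (LVQ1)


@dataclass
class SNNConfig:
    prototypes_per_class: int = 3
    epochs: int = 200
    lr_start: float = 0.3
    lr_end: float = 0.01


class SNNModel(ClassifierModel):
    kind = "SNN"

    def __init__(self, classes, prototypes, proto_class_idx, scaler, n_features):
        self.classes = classes
        self.prototypes = np.asarray(prototypes)
        self.proto_class_idx = np.asarray(proto_class_idx)
        self.scaler = scaler
        self.n_features = n_features
        self.selected = np.arange(n_features)

    def _score_matrix(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X)
        dist = np.sqrt(
            ((Z[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        )
        per_class = np.stack(
            [
                dist[:, self.proto_class_idx == j].min(axis=1)
                for j in range(len(self.classes))
            ],
            axis=1,
        )
        return _inverse_distance_scores(per_class)


def train_snn(
    X: np.ndarray,
    y,
    config: SNNConfig | None = None,
    seed: int = 0,
    classes: list[str] | None = None,
) -> SNNModel:
    """LVQ1: k-means-initialised prototypes, attract/repel updates."""
    config = config or SNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_finite(X)
    order = _class_order(y, classes)
    ppc = config.prototypes_per_class
    _require_min_per_class(y, order, ppc)
    scaler = _Scaler.fit(X)
    Z = scaler.transform(X)
    y_idx = np.array([order.index(c) for c in y])

    protos, proto_cls = [], []
    for j, c in enumerate(order):
        pts = Z[y_idx == j]
        if ppc == 1:
            centers = pts.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=ppc, n_init=4, random_state=seed % (2**31))
            km.fit(pts)
            centers = km.cluster_centers_
        protos.append(centers)
        proto_cls.extend([j] * ppc)
    prototypes = np.vstack(protos)
    proto_cls = np.array(proto_cls)

    rng = np.random.default_rng(seed)
    total = max(config.epochs * Z.shape[0] - 1, 1)
    # LVQ1 repulsion diverges on non-separable data; constraining the
    # prototypes to the training-data bounding box prevents the runaway
    # without affecting separable problems.
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    t = 0
    for _ in range(config.epochs):
        for i in rng.permutation(Z.shape[0]):
            lr = config.lr_start + (config.lr_end - config.lr_start) * t / total
            diff = prototypes - Z[i]
            w = int(np.argmin((diff**2).sum(axis=1)))
            if proto_cls[w] == y_idx[i]:
                prototypes[w] += lr * (Z[i] - prototypes[w])
            else:
                prototypes[w] -= lr * (Z[i] - prototypes[w])
                np.clip(prototypes[w], lo, hi, out=prototypes[w])
            t += 1
    return SNNModel(order, prototypes, proto_cls, scaler, X.shape[1])


# ---------------------------------------------------------------------------
# GA — genetic-algorithm feature selection over a nearest-centroid base


@dataclass
class GAConfig:
    subset_min: int = 3
    subset_max: int = 15
    population: int = 40
    generations: int = 50
    crossover_p: float = 0.8
    mutation_p: float = 0.05
    tournament: int = 3
    cv_folds: int = 3


class GAModel(ClassifierModel):
    kind = "GA"

    def __init__(self, classes, selected, centroids, scaler, n_features, fitness):
        self.classes = classes
        self.selected = np.asarray(selected)
        self.centroids = np.asarray(centroids)  # (n_classes, k) standardized
        self.scaler = scaler  # fitted on the selected columns
        self.n_features = n_features
        self.fitness = fitness

    def _score_matrix(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X[:, self.selected])
        dist = np.sqrt(
            ((Z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        )
        return _inverse_distance_scores(dist)


def centroid_cv_fitness(
    X: np.ndarray,
    y_idx: np.ndarray,
    feature_idx: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_classes: int,
) -> float:
    """Stratified-CV accuracy of a nearest-centroid classifier on a subset.

    Standardization is fitted on the training folds only.  This is the GA
    fitness function and doubles as the exhaustive-search oracle metric.
    """
    correct = 0
    total = 0
    for tr, te in folds:
        Xtr = X[np.ix_(tr, feature_idx)]
        Xte = X[np.ix_(te, feature_idx)]
        scaler = _Scaler.fit(Xtr)
        Ztr, Zte = scaler.transform(Xtr), scaler.transform(Xte)
        centroids = np.vstack(
            [Ztr[y_idx[tr] == j].mean(axis=0) for j in range(n_classes)]
        )
        dist = ((Zte[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred = np.argmin(dist, axis=1)
        correct += int((pred == y_idx[te]).sum())
        total += len(te)
    return correct / total


def _make_folds(y_idx: np.ndarray, n_splits: int, seed: int):
    n_splits = min(n_splits, int(np.bincount(y_idx).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=seed % (2**31))
    return list(skf.split(np.zeros_like(y_idx), y_idx))


def _repair(mask: np.ndarray, smin: int, smax: int,
            rng: np.random.Generator) -> np.ndarray:
    size = int(mask.sum())
    if size < smin:
        off = np.flatnonzero(~mask)
        add = rng.choice(off, size=smin - size, replace=False)
        mask[add] = True
    elif size > smax:
        on = np.flatnonzero(mask)
        drop = rng.choice(on, size=size - smax, replace=False)
        mask[drop] = False
    return mask


def train_ga(
    X: np.ndarray,
    y,
    config: GAConfig | None = None,
    seed: int = 0,
    classes: list[str] | None = None,
) -> GAModel:
    """Evolve a cluster subset maximising internal CV accuracy."""
    config = config or GAConfig()
    if config.population < 4:
        raise ValueError("population must be >= 4")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_finite(X)
    order = _class_order(y, classes)
    _require_min_per_class(y, order, 2)
    m = X.shape[1]
    smin = max(1, min(config.subset_min, m))
    smax = max(smin, min(config.subset_max, m))
    if m < smin:
        raise ValueError("matrix has fewer clusters than the subset size")
    y_idx = np.array([order.index(c) for c in y])

    rng = np.random.default_rng(seed)
    folds = _make_folds(y_idx, config.cv_folds, seed=seed + 1)
    memo: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in memo:
            memo[key] = centroid_cv_fitness(
                X, y_idx, np.flatnonzero(mask), folds, len(order)
            )
        return memo[key]

    population = []
    for _ in range(config.population):
        size = int(rng.integers(smin, smax + 1))
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=size, replace=False)] = True
        population.append(mask)

    def best_of(pop):
        fits = np.array([fitness(p) for p in pop])
        # ties resolved toward smaller subsets, then population order
        sizes = np.array([p.sum() for p in pop])
        best = np.lexsort((sizes, -fits))[0]
        return pop[best], float(fits[best])

    elite, elite_fit = best_of(population)
    for _ in range(config.generations):
        children = [elite.copy()]
        while len(children) < config.population:
            parents = []
            for _ in range(2):
                idx = rng.choice(len(population), size=config.tournament,
                                 replace=False)
                fits = [fitness(population[i]) for i in idx]
                parents.append(population[idx[int(np.argmax(fits))]].copy())
            p1, p2 = parents
            if rng.random() < config.crossover_p:
                swap = rng.random(m) < 0.5
                c1 = np.where(swap, p2, p1)
                c2 = np.where(swap, p1, p2)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                flip = rng.random(m) < config.mutation_p
                child = child ^ flip
                child = _repair(child, smin, smax, rng)
                if len(children) < config.population:
                    children.append(child)
        population = children
        gen_best, gen_fit = best_of(population)
        if gen_fit > elite_fit:
            elite, elite_fit = gen_best, gen_fit

    selected = np.flatnonzero(elite)
    scaler = _Scaler.fit(X[:, selected])
    Z = scaler.transform(X[:, selected])
    centroids = np.vstack(
        [Z[y_idx == j].mean(axis=0) for j in range(len(order))]
    )
    return GAModel(order, selected, centroids, scaler, m, elite_fit)


# ---------------------------------------------------------------------------
# Validation


def _require_min_per_class(y: np.ndarray, classes: list[str], k: int) -> None:
    for c in classes:
        if int((y == c).sum()) < k:
            raise ValueError(f"class {c!r} has fewer than {k} samples")


@dataclass
class ValidationReport:
    """Cross-validation, recognition capability and per-class rates."""

    model_kind: str
    classes: list[str]
    n: int
    cross_validation_pct: float
    recognition_pct: float
    cv_per_class_pct: dict[str, float]
    recognition_per_class_pct: dict[str, float]
    cv_confusion: dict[str, dict[str, int]]
    recognition_confusion: dict[str, dict[str, int]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(**json.loads(text))

    def to_frame(self) -> pd.DataFrame:
        """Report-table layout: validation rows x one model column."""
        rows = {
            "Cross-validation (%)": self.cross_validation_pct,
            "Recognition capability (%)": self.recognition_pct,
        }
        for c in self.classes:
            rows[f"Correct classified (%): {c}"] = self.cv_per_class_pct[c]
        return pd.DataFrame({self.model_kind: rows})


def _rates(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]):
    overall = 100.0 * float((y_true == y_pred).mean())
    per_class = {}
    confusion: dict[str, dict[str, int]] = {}
    for c in classes:
        mask = y_true == c
        per_class[c] = (
            100.0 * float((y_pred[mask] == c).mean()) if mask.any() else float("nan")
        )
        confusion[c] = {
            d: int((y_pred[mask] == d).sum()) for d in classes
        }
    return overall, per_class, confusion


def loocv(trainer, X: np.ndarray, y, classes: list[str] | None = None):
    """Leave-one-out cross-validation with full retraining per fold.

    ``trainer`` is a callable ``(X, y) -> model`` capturing its own config
    and seed, so feature selection happens inside every fold.  Returns
    (percent correct, per-class percent, confusion counts).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    order = _class_order(y, classes)
    _require_min_per_class(y, order, 2)
    preds = []
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        model = trainer(X[keep], y[keep])
        preds.append(model.predict(X[i: i + 1])[0])
    return _rates(y, np.array(preds), order)


def recognition_capability(model: ClassifierModel, X: np.ndarray, y):
    """Percent of training samples the final model classifies correctly."""
    y = np.asarray(y)
    preds = model.predict(np.asarray(X, dtype=float))
    return _rates(y, preds, model.classes)


def make_trainer(kind: str, config=None, seed: int = 0,
                 classes: list[str] | None = None):
    """A ``(X, y) -> model`` callable for the given model kind."""
    kind = kind.upper()
    if kind == "QC":
        return lambda X, y: train_qc(X, y, config, classes=classes)
    if kind == "SNN":
        return lambda X, y: train_snn(X, y, config, seed=seed, classes=classes)
    if kind == "GA":
        return lambda X, y: train_ga(X, y, config, seed=seed, classes=classes)
    raise ValueError(f"unknown model kind {kind!r}")


def validate(
    kind: str,
    matrix: PeakClusterMatrix | None = None,
    X: np.ndarray | None = None,
    y=None,
    config=None,
    seed: int = 0,
    classes: list[str] | None = None,
) -> ValidationReport:
    """Train, then report LOOCV %, recognition % and per-class rates."""
    if matrix is not None:
        X = matrix.intensities.to_numpy(dtype=float)
        y = matrix.labels.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    order = _class_order(y, classes)
    trainer = make_trainer(kind, config, seed=seed, classes=order)
    model = trainer(X, y)
    rec, rec_class, rec_conf = recognition_capability(model, X, y)
    cv, cv_class, cv_conf = loocv(trainer, X, y, classes=order)
    return ValidationReport(
        model_kind=kind.upper(),
        classes=order,
        n=len(y),
        cross_validation_pct=cv,
        recognition_pct=rec,
        cv_per_class_pct=cv_class,
        recognition_per_class_pct=rec_class,
        cv_confusion=cv_conf,
        recognition_confusion=rec_conf,
    )
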