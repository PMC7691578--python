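"""Decode optimizer individuals into feature subsets and score them.

An individual is a real weight vector over positions of the (SNE-reordered)
feature sequence. A feature enters the subset S when its weight is at least
the threshold t (default 0.5). The score is stratified 5-fold
cross-validated multi-class accuracy of a pluggable scikit-learn
classifier on the columns restricted to S, minus a size penalty
alpha * max(0, |S| - Upsilon) / D that activates above the target subset
size Upsilon. An empty decode receives the sentinel score -1 so the
optimizer is repelled from degenerate individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .expression import ExpressionMatrix, LabelVector

__all__ = [
    "DecoderConfig",
    "ClassifierSpec",
    "ObjectiveConfig",
    "FeatureSet",
    "decode",
    "cv_accuracy",
    "objective_value",
    "SubsetObjective",
]

EMPTY_SET_SENTINEL = -1.0


@dataclass(frozen=True)
class FeatureSet:
    """Sorted tuple of selected feature indices (0-based, original numbering)."""

    indices: tuple[int, ...]

    def __init__(self, indices) -> None:
        object.__setattr__(self, "indices", tuple(sorted(set(int(i) for i in indices))))

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __contains__(self, i) -> bool:
        return int(i) in set(self.indices)


@dataclass
class DecoderConfig:
    """Mapping from weight vectors to feature subsets.

    ``per_feature`` mode uses one weight per feature (H = D). ``anchors``
    mode spreads H anchor positions evenly along the reordered feature
    sequence; each feature inherits the weight of its nearest anchor
    (ties to the lower anchor).
    """

    n_features: int
    feature_order: np.ndarray | None = None
    threshold: float = 0.5
    mode: str = "per_feature"
    n_weights: int | None = None

    def __post_init__(self) -> None:
        D = self.n_features
        if self.feature_order is None:
            self.feature_order = np.arange(D)
        self.feature_order = np.asarray(self.feature_order, dtype=int)
        if sorted(self.feature_order.tolist()) != list(range(D)):
            raise ValueError("feature_order must be a permutation of 0..D-1")
        if self.mode not in ("per_feature", "anchors"):
            raise ValueError(f"unknown decode mode {self.mode!r}")
        if self.n_weights is None:
            self.n_weights = D if self.mode == "per_feature" else D
        if self.n_weights > D:
            raise ValueError("number of weights H cannot exceed number of features D")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def decode(individual: np.ndarray, decoder: DecoderConfig) -> FeatureSet:
    """Translate a weight vector into the selected feature subset."""
    w = np.asarray(individual, dtype=float)
    H, D = decoder.n_weights, decoder.n_features
    if w.shape != (H,):
        raise ValueError(f"individual must have length {H}, got {w.shape}")
    order = decoder.feature_order
    if decoder.mode == "per_feature":
        selected_positions = np.flatnonzero(w >= decoder.threshold)
    else:
        anchors = np.linspace(0, D - 1, H)
        positions = np.arange(D)
        dist = np.abs(positions[:, None] - anchors[None, :])
        nearest = np.argmin(dist, axis=1)  # argmin ties -> lower anchor
        selected_positions = np.flatnonzero(w[nearest] >= decoder.threshold)
    return FeatureSet(order[selected_positions])


def build_classifier(spec: "ClassifierSpec"):
    params = dict(spec.params)
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 50), random_state=spec.seed, **params
        )
    if spec.kind == "svm_rbf":
        return SVC(
            kernel="rbf",
            gamma=params.pop("gamma", 0.05),
            C=params.pop("C", 1.0),
            random_state=spec.seed,
            **params,
        )
    if spec.kind == "naive_bayes":
        return GaussianNB(**params)
    if spec.kind == "knn":
        # brute-force search avoids per-fold tree builds, which dominate on
        # the small sample sizes this objective is evaluated at
        return KNeighborsClassifier(
            n_neighbors=params.pop("n_neighbors", 5),
            algorithm=params.pop("algorithm", "brute"),
            **params,
        )
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "knn"
    params: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(sorted(dict(self.params).items())))
        build_classifier(self)  # validate eagerly


@dataclass
class ObjectiveConfig:
    """Penalty and cross-validation settings of the subset score."""

    n_features: int
    alpha: float = 0.5
    upsilon: int | None = None  # target subset size; defaults to min(10, D)
    cv_folds: int = 5
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.upsilon is None:
            self.upsilon = min(10, self.n_features)
        if not 1 <= self.upsilon <= self.n_features:
            raise ValueError("need 1 <= upsilon <= D")


def cv_accuracy(
    X: ExpressionMatrix | np.ndarray,
    y: LabelVector | np.ndarray,
    S: FeatureSet,
    clf: ClassifierSpec,
    cfg: ObjectiveConfig,
    _cache: dict | None = None,
) -> float:
    """Stratified k-fold CV accuracy on the columns restricted to S.

    Overall (micro) accuracy: correctly classified held-out samples over
    all samples, pooled across folds. Deterministic given the fold seed and
    classifier seed; memoized in ``_cache`` when provided.
    """
    if len(S) == 0:
        raise ValueError("cannot score an empty feature set")
    key = (S.indices, clf)
    if _cache is not None and key in _cache:
        return _cache[key]
    if isinstance(X, ExpressionMatrix):
        values = X.values
        labels = y.aligned_to(X.sample_ids) if isinstance(y, LabelVector) else np.asarray(y)
    else:
        values = np.asarray(X, dtype=float)
        labels = np.asarray(y)
    data = values[list(S.indices)].T  # samples x selected features
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < cfg.cv_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples; "
            f"reduce cv_folds below {cfg.cv_folds}"
        )
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.cv_seed)
    correct = 0
    for train, test in skf.split(data, labels):
        model = build_classifier(clf)
        model.fit(data[train], labels[train])
        correct += int(np.sum(model.predict(data[test]) == labels[test]))
    acc = correct / len(labels)
    if _cache is not None:
        _cache[key] = acc
    return acc


def objective_value(accuracy: float, set_size: int, cfg: ObjectiveConfig) -> float:
    """Penalized score: accuracy - alpha * max(0, |S| - Upsilon) / D."""
    if set_size == 0:
        return EMPTY_SET_SENTINEL
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    return accuracy - cfg.alpha * max(0, set_size - cfg.upsilon) / cfg.n_features


class SubsetObjective:
    """Callable objective for the optimizer: weight vector -> penalized score."""

    def __init__(
        self,
        X: ExpressionMatrix | np.ndarray,
        y,
        decoder: DecoderConfig,
        classifier: ClassifierSpec,
        config: ObjectiveConfig,
    ) -> None:
        self.X = X
        self.y = y
        self.decoder = decoder
        self.classifier = classifier
        self.config = config
        self.cache: dict = {}
        self.n_evaluations = 0

    def decode(self, individual: np.ndarray) -> FeatureSet:
        return decode(individual, self.decoder)

    def score_set(self, S: FeatureSet) -> float:
        if len(S) == 0:
            return EMPTY_SET_SENTINEL
        acc = cv_accuracy(self.X, self.y, S, self.classifier, self.config, self.cache)
        return objective_value(acc, len(S), self.config)

    def __call__(self, individual: np.ndarray) -> float:
        self.n_evaluations += 1
        return self.score_set(self.decode(individual))
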