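"""Classifier registry, the eight-model core, metrics and feature analyses.

Fourteen classifier families are registered (linear, margin, tree-ensemble,
probabilistic, neighbour, discriminant and neural approaches). Each family
is fitted by grid search with internal stratified cross-validation. The
operational core is the eight families whose published accuracies exceeded
0.99: gradient boosting, SVM, AdaBoost, logistic regression, stacking,
random forest, bagging and a multi-layer perceptron, in that fixed member
order.

Scale-sensitive families sit behind a z-score standardizer fitted on the
training split only; tree ensembles consume raw features. The stacking
member combines the other seven core families under a logistic
meta-learner. All randomness flows from one top-level seed, split
deterministically per component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    StratifiedShuffleSplit,
    train_test_split,
)
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from nabh.features import FEATURE_NAMES, FeatureVector

#: Member order of the operational core (fixed; mirrors the published server).
CORE_FAMILIES: tuple[str, ...] = (
    "gradient_boosting",
    "svm",
    "ada_boost",
    "logistic_regression",
    "stacking",
    "random_forest",
    "bagging",
    "mlp",
)

#: Families fitted on raw features (scale-invariant tree ensembles).
_TREE_FAMILIES = frozenset(
    {"gradient_boosting", "ada_boost", "random_forest", "bagging"}
)

ALL_FAMILIES: tuple[str, ...] = CORE_FAMILIES + (
    "ridge",
    "naive_bayes",
    "bernoulli_nb",
    "lda",
    "qda",
    "knn",
)

MANIFEST_NAME = "manifest.txt"


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass
class LabelledDataset:
    """Feature matrix + boolean labels (+ provenance ids) for training."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if not (len(self.X) == len(self.y) == len(self.ids)):
            raise ValueError("X, y and ids must have equal lengths")

    @classmethod
    def from_vectors(
        cls,
        vectors: Sequence[FeatureVector],
        labels: Sequence[bool],
        ids: Sequence[str],
    ) -> "LabelledDataset":
        X = np.array([v.values for v in vectors], dtype=float)
        return cls(X=X, y=np.asarray(labels, dtype=bool), ids=list(ids))

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, indices: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(
            X=self.X[indices], y=self.y[indices], ids=[self.ids[i] for i in indices]
        )


def split_dataset(
    data: LabelledDataset, test_fraction: float, seed: int
) -> tuple[LabelledDataset, LabelledDataset]:
    """Deterministic stratified train/test split (default protocol: 70/30)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    classes, counts = np.unique(data.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 2:
        raise ValueError("each class needs at least two members to stratify")
    idx = np.arange(len(data))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=data.y,
        shuffle=True,
    )
    return data.subset(train_idx), data.subset(test_idx)


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One candidate family with its hyperparameter grid and seed."""

    family: str
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.grid:
            object.__setattr__(self, "grid", default_grid(self.family))
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def _stacking_members(seed: int) -> list[tuple[str, Pipeline]]:
    """The other seven core families, lightly configured, for stacking."""
    members = []
    for i, family in enumerate(f for f in CORE_FAMILIES if f != "stacking"):
        est = _bare_estimator(family, seed + 17 * (i + 1))
        members.append((family, _wrap(family, est)))
    return members


def _bare_estimator(family: str, seed: int):
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "svm":
        return SVC(random_state=seed)
    if family == "ada_boost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "stacking":
        return StackingClassifier(
            estimators=_stacking_members(seed),
            final_estimator=LogisticRegression(max_iter=2000, random_state=seed),
            cv=3,
            n_jobs=None,
        )
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if family == "bagging":
        return BaggingClassifier(n_estimators=25, random_state=seed)
    if family == "mlp":
        return MLPClassifier(max_iter=500, random_state=seed)
    if family == "ridge":
        return RidgeClassifier(random_state=seed)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "bernoulli_nb":
        return BernoulliNB(binarize=0.0)
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "qda":
        return QuadraticDiscriminantAnalysis()
    if family == "knn":
        return KNeighborsClassifier()
    raise ValueError(f"unknown model family {family!r}")


def _wrap(family: str, estimator) -> Pipeline:
    """Pipeline with a standardizer for scale-sensitive families."""
    scale = "passthrough" if family in _TREE_FAMILIES else StandardScaler()
    return Pipeline([("scale", scale), ("clf", estimator)])


def default_grid(family: str) -> dict[str, list]:
    """Modest default grids per family (overridable via ModelSpec.grid)."""
    grids: dict[str, dict[str, list]] = {
        "gradient_boosting": {"clf__n_estimators": [100, 300]},
        "svm": {"clf__C": [0.1, 1.0, 10.0], "clf__kernel": ["rbf", "linear"]},
        "ada_boost": {"clf__n_estimators": [50, 100]},
        "logistic_regression": {"clf__C": [0.1, 1.0, 10.0]},
        "stacking": {"clf__final_estimator__C": [1.0]},
        "random_forest": {"clf__n_estimators": [100, 300]},
        "bagging": {"clf__n_estimators": [25, 50]},
        "mlp": {"clf__hidden_layer_sizes": [(16,), (64,)]},
        "ridge": {"clf__alpha": [0.1, 1.0, 10.0]},
        "naive_bayes": {"clf__var_smoothing": [1e-9]},
        "bernoulli_nb": {"clf__alpha": [0.1, 1.0]},
        "lda": {"clf__solver": ["svd"]},
        "qda": {"clf__reg_param": [0.0, 1e-3]},
        "knn": {"clf__n_neighbors": [3, 5, 11]},
    }
    return grids[family]


@dataclass
class FittedModel:
    """A grid-search winner: hard class calls plus a decision score for AUC."""

    family: str
    estimator: Pipeline
    best_params: dict
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=bool)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            try:
                return np.asarray(est.decision_function(X), dtype=float)
            except AttributeError:  # pipeline final step lacks it
                pass
        return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def train_model(spec: ModelSpec, train: LabelledDataset) -> FittedModel:
    """Fit one family by grid search with internal 3-fold stratified CV."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data must contain both classes")
    pipeline = _wrap(spec.family, _bare_estimator(spec.family, spec.seed))
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=spec.seed)
    _, fold_counts = np.unique(train.y, return_counts=True)
    if fold_counts.min() < cv.get_n_splits():
        raise ValueError(
            f"minority class has {fold_counts.min()} members; "
            f"cannot form {cv.get_n_splits()} stratified folds"
        )
    search = GridSearchCV(
        pipeline,
        dict(spec.grid),
        scoring="accuracy",
        cv=cv,
        n_jobs=None,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(train.X, train.y)
    return FittedModel(
        family=spec.family,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus accuracy / weighted precision-recall-F1 / AUC."""

    TP: int
    FP: int
    FN: int
    TN: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None = None
    cv_accuracy_mean: float | None = None
    cv_accuracy_std: float | None = None

    @property
    def confusion_matrix(self) -> list[list[int]]:
        return [[self.TP, self.FP], [self.FN, self.TN]]


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; defining it as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(TP: int, FP: int, FN: int, TN: int) -> MetricsReport:
    """Accuracy and support-weighted precision/recall/F1 from a confusion matrix.

    Weighted averaging (supports: positive = TP+FN, negative = FP+TN) makes
    weighted recall identically equal to accuracy.
    """
    if min(TP, FP, FN, TN) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = TP + FP + FN + TN
    if total == 0:
        raise ValueError("confusion matrix is empty")
    support_pos = TP + FN
    support_neg = FP + TN

    prec_pos = _safe_div(TP, TP + FP, "positive precision")
    prec_neg = _safe_div(TN, TN + FN, "negative precision")
    rec_pos = _safe_div(TP, TP + FN, "positive recall")
    rec_neg = _safe_div(TN, TN + FP, "negative recall")
    f1_pos = _safe_div(2 * prec_pos * rec_pos, prec_pos + rec_pos, "positive F1")
    f1_neg = _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg, "negative F1")

    def weighted(pos: float, neg: float) -> float:
        return (support_pos * pos + support_neg * neg) / total

    return MetricsReport(
        TP=TP, FP=FP, FN=FN, TN=TN,
        accuracy=(TP + TN) / total,
        precision=weighted(prec_pos, prec_neg),
        recall=weighted(rec_pos, rec_neg),
        f1=weighted(f1_pos, f1_neg),
    )


def evaluate(model: FittedModel, test: LabelledDataset) -> MetricsReport:
    """Confusion matrix + metrics on a held-out split; AUC from decision scores."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    if len(np.unique(test.y)) < 2:
        raise ValueError("AUC is undefined on a single-class test set")
    pred = model.predict(test.X)
    y = test.y
    TP = int(np.sum(pred & y))
    FP = int(np.sum(pred & ~y))
    FN = int(np.sum(~pred & y))
    TN = int(np.sum(~pred & ~y))
    base = metrics_from_confusion(TP, FP, FN, TN)
    auc = float(roc_auc_score(y, model.decision_scores(test.X)))
    return MetricsReport(
        TP=TP, FP=FP, FN=FN, TN=TN,
        accuracy=base.accuracy, precision=base.precision,
        recall=base.recall, f1=base.f1, auc_roc=auc,
    )


def cross_validate(
    spec: ModelSpec,
    data: LabelledDataset,
    iterations: int = 50,
    seed: int = 0,
    params: Mapping[str, object] | None = None,
    return_scores: bool = False,
):
    """Repeated stratified 70/30 shuffle-split accuracy (mean, std).

    The model is fitted at fixed hyperparameters per iteration: ``params``
    if given, otherwise the first candidate of each grid dimension. With a
    fixed seed the split sequence is reproducible, and extending
    ``iterations`` reproduces the earlier scores as a prefix.
    """
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    pipeline = _wrap(spec.family, _bare_estimator(spec.family, spec.seed))
    fixed = dict(params) if params else {k: v[0] for k, v in spec.grid.items()}
    pipeline.set_params(**fixed)
    splitter = StratifiedShuffleSplit(
        n_splits=iterations, test_size=0.3, random_state=seed
    )
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in splitter.split(data.X, data.y):
            est = clone(pipeline)
            est.fit(data.X[train_idx], data.y[train_idx])
            scores.append(float(est.score(data.X[test_idx], data.y[test_idx])))
    arr = np.asarray(scores)
    if return_scores:
        return float(arr.mean()), float(arr.std()), scores
    return float(arr.mean()), float(arr.std())


# ---------------------------------------------------------------------------
# The eight-model core
# ---------------------------------------------------------------------------


def _member_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class TrainedEnsemble:
    """The fitted core in fixed member order, plus training metadata."""

    members: list[FittedModel]
    feature_order: tuple[str, ...]
    seed: int
    scales_fingerprint: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.feature_order) != FEATURE_NAMES:
            raise ValueError("feature order does not match the canonical 20 names")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(m.family for m in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict_votes(self, X: np.ndarray) -> np.ndarray:
        """Per-member hard calls: boolean matrix (n_samples, n_members)."""
        return np.column_stack([m.predict(X) for m in self.members])

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write one serialized model per member plus a plain-text manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, member in enumerate(self.members):
            joblib.dump(member, path / f"member_{i}_{member.family}.joblib")
        lines = [
            f"n_members={self.n_members}",
            f"families={','.join(self.families)}",
            f"feature_order={','.join(self.feature_order)}",
            f"seed={self.seed}",
            f"scales_fingerprint={self.scales_fingerprint}",
        ]
        for i, member in enumerate(self.members):
            lines.append(f"best_params_{i}={member.best_params!r}")
        for key, value in sorted(self.metadata.items()):
            lines.append(f"meta_{key}={value}")
        (path / MANIFEST_NAME).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEnsemble":
        path = Path(path)
        manifest: dict[str, str] = {}
        for line in (path / MANIFEST_NAME).read_text().splitlines():
            if "=" in line:
                key, _, value = line.partition("=")
                manifest[key] = value
        families = manifest["families"].split(",")
        members = [
            joblib.load(path / f"member_{i}_{family}.joblib")
            for i, family in enumerate(families)
        ]
        return cls(
            members=members,
            feature_order=tuple(manifest["feature_order"].split(",")),
            seed=int(manifest["seed"]),
            scales_fingerprint=manifest.get("scales_fingerprint", ""),
            metadata={
                k[5:]: v for k, v in manifest.items() if k.startswith("meta_")
            },
        )


def train_ensemble(
    train: LabelledDataset,
    seed: int = 0,
    families: Sequence[str] = CORE_FAMILIES,
    scales_fingerprint: str = "",
) -> TrainedEnsemble:
    """Grid-search-fit every requested family; members keep the given order."""
    seeds = _member_seeds(seed, len(families))
    members = [
        train_model(ModelSpec(family=family, seed=member_seed), train)
        for family, member_seed in zip(families, seeds)
    ]
    return TrainedEnsemble(
        members=members,
        feature_order=FEATURE_NAMES,
        seed=seed,
        scales_fingerprint=scales_fingerprint,
        metadata={"n_train": len(train)},
    )


# ---------------------------------------------------------------------------
# Feature analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelevanceTable:
    """Per-feature average relevance, as percentages summing to 100."""

    percentages: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.percentages) != set(FEATURE_NAMES):
            raise ValueError("relevance table must cover exactly the 20 features")

    def ranking(self) -> list[str]:
        """Feature names from most to least relevant (ties broken by name)."""
        return sorted(self.percentages, key=lambda k: (-self.percentages[k], k))

    def top(self, k: int) -> list[tuple[str, float]]:
        return [(name, self.percentages[name]) for name in self.ranking()[:k]]


def feature_relevance(
    ensemble: TrainedEnsemble,
    data: LabelledDataset,
    seed: int = 0,
    repeats: int = 10,
) -> RelevanceTable:
    """Permutation importance averaged over the ensemble members.

    Per member and feature, the accuracy drop under ``repeats`` column
    shuffles is measured, clipped at zero, averaged across members and
    normalized to percentages summing to 100. A feature with identical
    values in every sample gets exactly zero.
    """
    seeds = _member_seeds(seed, ensemble.n_members)
    stacked = np.zeros(len(FEATURE_NAMES))
    for member, member_seed in zip(ensemble.members, seeds):
        result = permutation_importance(
            member.estimator,
            data.X,
            data.y,
            scoring="accuracy",
            n_repeats=repeats,
            random_state=member_seed,
            n_jobs=None,
        )
        stacked += np.clip(result.importances_mean, 0.0, None)
    stacked /= ensemble.n_members
    total = stacked.sum()
    if total == 0:
        warnings.warn("no feature shows positive permutation relevance", stacklevel=2)
        percentages = dict.fromkeys(FEATURE_NAMES, 0.0)
    else:
        percentages = {
            name: 100.0 * value / total
            for name, value in zip(FEATURE_NAMES, stacked)
        }
    return RelevanceTable(percentages=percentages)


@dataclass(frozen=True)
class SaturationPoint:
    k: int
    family: str
    accuracy: float


def feature_saturation(
    data: LabelledDataset,
    k_range: Sequence[int],
    seed: int = 0,
    families: Sequence[str] = CORE_FAMILIES,
    ranking: Sequence[str] | None = None,
    test_fraction: float = 0.3,
) -> list[SaturationPoint]:
    """Accuracy of each core family retrained on the top-k features.

    Features are taken in relevance order (``ranking``; computed from a
    freshly trained full-feature ensemble when not supplied) but kept in
    canonical column order, so k = 20 is exactly the full-feature run.
    """
    if any(k < 1 or k > len(FEATURE_NAMES) for k in k_range):
        raise ValueError("k_range entries must lie in [1, 20]")
    train, test = split_dataset(data, test_fraction, seed)
    if ranking is None:
        full = train_ensemble(train, seed=seed, families=families)
        ranking = feature_relevance(full, test, seed=seed).ranking()
    name_to_col = {name: i for i, name in enumerate(FEATURE_NAMES)}
    points: list[SaturationPoint] = []
    seeds = _member_seeds(seed, len(families))
    for k in k_range:
        cols = sorted(name_to_col[name] for name in ranking[:k])
        sub_train = LabelledDataset(train.X[:, cols], train.y, train.ids)
        sub_test = LabelledDataset(test.X[:, cols], test.y, test.ids)
        for family, member_seed in zip(families, seeds):
            model = train_model(ModelSpec(family=family, seed=member_seed), sub_train)
            accuracy = float(np.mean(model.predict(sub_test.X) == sub_test.y))
            points.append(SaturationPoint(k=k, family=family, accuracy=accuracy))
    return points
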