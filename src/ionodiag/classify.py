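"""Predict high/low tuber-yield class from clr-transformed leaf ionomes.

Three classifier families are compared — k-nearest neighbours, random
forest and a radial-kernel support vector machine — each tuned by k-fold
cross-validated accuracy over a small grid and refit on the full training
set. Splitting is stratified at cultivar level: every cultivar contributes
the same fraction of its samples to the training set, so poorly documented
cultivars are present on both sides whenever their sample size permits.

Polarity follows medical diagnostics: *positive = low yield = intervention
needed*. A true negative is an observed high-yielder correctly predicted
high — a nutritionally balanced specimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_perm_importance
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .pipeline import CLR_COLUMNS

__all__ = [
    "POSITIVE_CLASS", "NEGATIVE_CLASS", "ALGORITHMS",
    "SplitSpec", "ConfusionCounts", "EvaluationReport", "TrainedModel",
    "FeatureImportance", "split_by_cultivar", "train_classifier",
    "predict", "evaluate", "permutation_importance", "random_classifier_test",
]

POSITIVE_CLASS = "low"   # needs intervention
NEGATIVE_CLASS = "high"  # balanced
ALGORITHMS = ("knn", "rf", "svm")


@dataclass(frozen=True)
class SplitSpec:
    """Cultivar-stratified train/test split parameters."""

    train_fraction: float = 0.75
    seed: int = 0
    key: str = "cultivar"


@dataclass(frozen=True)
class ConfusionCounts:
    """2×2 confusion counts with positive = low yield.

    tp: observed low predicted low; fp: observed high predicted low;
    fn: observed low predicted high; tn: observed high predicted high.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.total


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set evaluation: overall and per-cultivar accuracy."""

    model_id: str
    counts: ConfusionCounts
    accuracy: float
    per_cultivar: pd.DataFrame  # columns: cultivar, n, accuracy
    cv_folds: int


@dataclass(frozen=True)
class TrainedModel:
    """A tuned classifier together with its training provenance."""

    estimator: object
    algorithm: str
    features: tuple[str, ...]
    cv_accuracy: float
    best_params: dict
    folds: int
    seed: int


@dataclass(frozen=True)
class FeatureImportance:
    """Permutation importance of one feature: mean accuracy drop ± SE."""

    feature: str
    importance: float
    se: float
    negligible: bool


def split_by_cultivar(
    df: pd.DataFrame,
    fraction: float = 0.75,
    seed: int = 0,
    key: str = "cultivar",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random per-cultivar split into training and testing frames.

    Within each cultivar ``round(n × fraction)`` records go to training
    (at least 1 and at most n − 1 when n ≥ 2, so both partitions see the
    cultivar). Single-record cultivars go to training with a warning.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    singletons = []
    for cultivar, grp in df.groupby(key, sort=True):
        idx = grp.index.to_numpy()
        n = idx.size
        if n == 1:
            singletons.append(cultivar)
            train_idx.extend(idx)
            continue
        n_train = int(np.clip(round(n * fraction), 1, n - 1))
        perm = rng.permutation(n)
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    if singletons:
        warnings.warn(
            f"{len(singletons)} single-record cultivars assigned to training "
            "only: " + ", ".join(map(str, singletons[:5])))
    return df.loc[sorted(train_idx)], df.loc[sorted(test_idx)]


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """RBF kernel width 1/(2 m²) with m the median pairwise distance."""
    if x.shape[0] > 1000:
        x = x[rng.choice(x.shape[0], 1000, replace=False)]
    m = float(np.median(pdist(x)))
    if m <= 0:
        return 1.0
    return 1.0 / (2.0 * m * m)


def _make_search(algorithm: str, x: np.ndarray, folds: int, seed: int) -> GridSearchCV:
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    if algorithm == "knn":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", KNeighborsClassifier())])
        grid = {"clf__n_neighbors": list(range(3, 22, 2))}
    elif algorithm == "rf":
        est = RandomForestClassifier(n_estimators=500, random_state=seed)
        grid = {"max_features": [1, 2, 3]}
    elif algorithm == "svm":
        rng = np.random.default_rng(seed)
        gamma = _median_heuristic_gamma(x, rng)
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", SVC(kernel="rbf", gamma=gamma, random_state=seed))])
        grid = {"clf__C": [0.25, 0.5, 1.0, 2.0, 4.0]}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return GridSearchCV(est, grid, scoring="accuracy", cv=cv, n_jobs=None)


def train_classifier(
    train: pd.DataFrame,
    algorithm: str = "knn",
    folds: int = 10,
    seed: int = 0,
    features: tuple[str, ...] = CLR_COLUMNS,
) -> TrainedModel:
    """Tune and fit one classifier family on clr features.

    Hyperparameters are selected by ``folds``-fold cross-validated accuracy
    over a small grid (kNN: k ∈ {3,5,…,21}; RF: 500 trees, per-split
    candidate features ∈ {1,2,3}; SVM: radial kernel, C ∈ {0.25,…,4},
    kernel width from the median heuristic); the winning configuration is
    refit on the full training set.
    """
    y = train["yield_class"].to_numpy(dtype=str)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if len(train) < folds:
        raise ValueError(f"need at least {folds} records for {folds}-fold CV")
    x = train.loc[:, list(features)].to_numpy(dtype=float)
    search = _make_search(algorithm, x, folds, seed)
    search.fit(x, y)
    return TrainedModel(
        estimator=search.best_estimator_,
        algorithm=algorithm,
        features=tuple(features),
        cv_accuracy=float(search.best_score_),
        best_params=dict(search.best_params_),
        folds=folds,
        seed=seed,
    )


def predict(model: TrainedModel, df: pd.DataFrame) -> np.ndarray:
    x = df.loc[:, list(model.features)].to_numpy(dtype=float)
    return model.estimator.predict(x).astype(str)


def evaluate(model: TrainedModel, test: pd.DataFrame) -> EvaluationReport:
    """Confusion counts, overall and per-cultivar accuracy on a test frame."""
    if len(test) == 0:
        raise ValueError("empty test set")
    y = test["yield_class"].to_numpy(dtype=str)
    yhat = predict(model, test)
    counts = ConfusionCounts(
        tp=int(((y == POSITIVE_CLASS) & (yhat == POSITIVE_CLASS)).sum()),
        fp=int(((y == NEGATIVE_CLASS) & (yhat == POSITIVE_CLASS)).sum()),
        fn=int(((y == POSITIVE_CLASS) & (yhat == NEGATIVE_CLASS)).sum()),
        tn=int(((y == NEGATIVE_CLASS) & (yhat == NEGATIVE_CLASS)).sum()),
    )
    correct = pd.Series(y == yhat, index=test.index)
    per = (
        correct.groupby(test["cultivar"])
        .agg(["size", "mean"])
        .reset_index()
        .rename(columns={"size": "n", "mean": "accuracy"})
    )
    return EvaluationReport(
        model_id=model.algorithm,
        counts=counts,
        accuracy=counts.accuracy,
        per_cultivar=per,
        cv_folds=model.folds,
    )


def permutation_importance(
    model: TrainedModel,
    df: pd.DataFrame,
    repeats: int = 20,
    seed: int = 0,
) -> list[FeatureImportance]:
    """Rank clr variables by mean accuracy drop under permutation.

    One feature at a time is shuffled while the others are left unchanged;
    the importance is the mean decrease in accuracy over ``repeats``
    shuffles. Features whose importance cannot be resolved from zero are
    flagged ``negligible`` (candidates for removal; none are removed
    automatically): the threshold is the larger of 2 standard errors over
    repeats and 1/√n, since an accuracy estimated on n rows cannot resolve
    importance differences below its own sampling noise. For an unbiased
    reading pass a frame the model was not trained on — on the training set
    itself a flexible model assigns small positive scores to memorised
    noise features.
    """
    x = df.loc[:, list(model.features)].to_numpy(dtype=float)
    y = df["yield_class"].to_numpy(dtype=str)
    res = _sk_perm_importance(
        model.estimator, x, y, scoring="accuracy",
        n_repeats=repeats, random_state=seed)
    se = res.importances_std / np.sqrt(repeats)
    floor = 1.0 / np.sqrt(len(df))
    out = [
        FeatureImportance(
            feature=f,
            importance=float(m),
            se=float(s),
            negligible=bool(abs(m) <= max(2 * s, floor)),
        )
        for f, m, s in zip(model.features, res.importances_mean, se)
    ]
    out.sort(key=lambda e: -e.importance)
    return out


def select_best_model(models: "list[TrainedModel]") -> TrainedModel:
    """Pick the most accurate model by mean CV accuracy; ties go to kNN.

    The winner supplies the reference bank for diagnosis — kNN is preferred
    on ties because neighbourhood structure is the most interpretable fit
    for a nearest-reference method.
    """
    if not models:
        raise ValueError("no models to select from")
    best = max(models,
               key=lambda m: (m.cv_accuracy, m.algorithm == "knn"))
    return best


def random_classifier_test(counts: ConfusionCounts) -> tuple[float, float]:
    """Chi-square goodness-of-fit of (correct, incorrect) against 50/50.

    Tests whether the classifier's success rate could come from a
    non-informative coin-flip classifier. Returns (statistic, p-value).
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    observed = [counts.n_correct, counts.total - counts.n_correct]
    statistic, p = stats.chisquare(observed)
    return float(statistic), float(p)
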