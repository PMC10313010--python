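"""Classical ("distribution") pair scorers.

Nine probabilistic classifiers are trained on fused pair features and
expose their positive-class probability as the similarity score:

====== =============================================================
name   model
====== =============================================================
svm    support vector classifier (RBF, Platt-scaled probabilities)
rf     random forest
ert    extremely randomized trees
knn    k-nearest neighbours
mnb    multinomial naive Bayes (features min-shifted to nonnegative)
gbdt   gradient-boosted trees
goss   gradient-boosting with gradient-based one-side sampling
dart   gradient-boosting with dropout-regularized trees
mlp    multilayer perceptron
====== =============================================================

Hyperparameters are chosen on the validation partition over a grid
controlled by ``gs_mode``: 0 = library defaults, 1 = coarse grid,
2 = full grid (at most 4 points per hyperparameter, <= 4^3 combinations
per model). Ties prefer the earliest grid point, so fits are
reproducible from (name, dataset, gs_mode, metric, seed) alone.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .base import PairScorer
from .data import RankingDataset, TaskSpec
from .features import PairFeatureScheme, default_scheme, pair_feature_matrix
from .metrics import MetricFlag, ScoredLabeledList, grouped_metric, parse_metric_flag

__all__ = ["DISTRIBUTION_MODELS", "DistributionScorer", "train_distribution_model"]

DISTRIBUTION_MODELS = ("svm", "rf", "ert", "knn", "mnb", "gbdt", "goss", "dart", "mlp")

_LGBM_COMMON = dict(
    n_estimators=100,
    deterministic=True,
    force_row_wise=True,
    num_threads=1,
    verbosity=-1,
)


def _make_estimator(name: str, seed: int, params: dict):
    if name == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1, **params)
    if name == "ert":
        return ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1, **params)
    if name == "knn":
        return KNeighborsClassifier(n_jobs=1, **params)
    if name == "mnb":
        return MultinomialNB(**params)
    if name == "mlp":
        return MLPClassifier(random_state=seed, max_iter=300, **params)
    if name in ("gbdt", "goss", "dart"):
        return LGBMClassifier(
            boosting_type=name, random_state=seed, **_LGBM_COMMON, **params
        )
    raise ValueError(
        f"unknown distribution model {name!r}; valid names: {', '.join(DISTRIBUTION_MODELS)}"
    )


# grid axes per family; gs_mode 1 truncates each axis to its first two points
_GRIDS: dict = {
    "svm": {"C": [1.0, 10.0, 0.1, 100.0], "gamma": ["scale", 0.1]},
    "rf": {"max_depth": [None, 8], "min_samples_leaf": [1, 3]},
    "ert": {"max_depth": [None, 8], "min_samples_leaf": [1, 3]},
    "knn": {"n_neighbors": [5, 15, 3, 9], "weights": ["uniform", "distance"]},
    "mnb": {"alpha": [1.0, 0.5, 0.1, 2.0]},
    "mlp": {"hidden_layer_sizes": [(64,), (64, 32)], "alpha": [1e-4, 1e-3]},
    "gbdt": {"num_leaves": [31, 15], "learning_rate": [0.1, 0.05]},
    "goss": {"num_leaves": [31, 15], "learning_rate": [0.1, 0.05]},
    "dart": {"num_leaves": [31, 15], "learning_rate": [0.1, 0.05]},
}


def _grid_points(name: str, gs_mode: int):
    if gs_mode == 0:
        return [{}]
    axes = _GRIDS[name]
    if gs_mode == 1:
        axes = {k: v[:2] for k, v in axes.items()}
    keys = list(axes)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(axes[k] for k in keys))]


class DistributionScorer(PairScorer):
    """A fitted classical classifier scoring pairs via predict_proba."""

    def __init__(
        self,
        name: str,
        estimator,
        scheme: PairFeatureScheme,
        seed: int,
        grid_point: dict,
        feature_shift: np.ndarray | None = None,
    ):
        super().__init__(seed=seed, metadata={"grid_point": grid_point})
        self.name = name
        self.estimator = estimator
        self.scheme = scheme
        self.feature_shift = feature_shift  # mnb nonnegativity shift

    def _features(self, pairs: Sequence[tuple], task: TaskSpec) -> np.ndarray:
        X = pair_feature_matrix(pairs, task, self.scheme)
        if self.feature_shift is not None:
            X = np.clip(X - self.feature_shift, 0.0, None)
        return X

    def score_pairs(self, pairs: Sequence[tuple], task: TaskSpec) -> np.ndarray:
        if len(pairs) == 0:
            return np.zeros(0)
        X = self._features(pairs, task)
        return self.estimator.predict_proba(X)[:, 1]

    def retrain(self, dataset: RankingDataset) -> "DistributionScorer":
        """Refit with the already-chosen hyperparameters on the dataset's
        current training partition (used for out-of-fold stacking scores)."""
        pairs, y, _ = dataset.pairs_in("train")
        X = pair_feature_matrix(pairs, dataset.task, self.scheme)
        shift = None
        if self.name == "mnb":
            shift = X.min(axis=0)
            X = np.clip(X - shift, 0.0, None)
        est = _make_estimator(self.name, self.seed, self.metadata["grid_point"])
        est.fit(X, y)
        return DistributionScorer(
            self.name, est, self.scheme, self.seed, self.metadata["grid_point"], shift
        )

    def __getstate__(self):
        return self.__dict__.copy()

    def __setstate__(self, state):
        self.__dict__.update(state)


def _validation_value(
    scorer: DistributionScorer, dataset: RankingDataset, flag: MetricFlag
) -> float:
    pairs, labels, gids = dataset.pairs_in("valid")
    scores = scorer.score_pairs(pairs, dataset.task)
    data = ScoredLabeledList(scores, labels, groups=gids)
    return grouped_metric(data, flag)


def train_distribution_model(
    name: str,
    dataset: RankingDataset,
    scheme: PairFeatureScheme | None = None,
    gs_mode: int = 0,
    metric: str = "auc",
    seed: int = 0,
) -> DistributionScorer:
    """Fit one classical scorer, choosing hyperparameters on validation.

    ``mnb`` requires nonnegative input; its features are shifted by the
    per-column training minimum (recorded in the scorer and re-applied,
    with clipping, at scoring time).
    """
    if name not in DISTRIBUTION_MODELS:
        raise ValueError(
            f"unknown distribution model {name!r}; valid names: "
            + ", ".join(DISTRIBUTION_MODELS)
        )
    if gs_mode not in (0, 1, 2):
        raise ValueError("gs_mode must be 0, 1 or 2")
    task = dataset.task
    if scheme is None:
        scheme = default_scheme(task)
    flag = parse_metric_flag(metric)

    train_pairs, y, _ = dataset.pairs_in("train")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("training partition must contain both classes")
    X = pair_feature_matrix(train_pairs, task, scheme)
    shift = None
    if name == "mnb":
        shift = X.min(axis=0)
        X = np.clip(X - shift, 0.0, None)

    best = None
    for point in _grid_points(name, gs_mode):
        est = _make_estimator(name, seed, point)
        est.fit(X, y)
        scorer = DistributionScorer(name, est, scheme, seed, point, feature_shift=shift)
        if len(_grid_points(name, gs_mode)) == 1:
            return scorer
        value = _validation_value(scorer, dataset, flag)
        if best is None or value > best[0]:
            best = (value, scorer)
    return best[1]
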