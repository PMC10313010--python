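"""Supervised integration of base scorers with LambdaMART.

Base pair-scorers are evaluated per (query, candidate) pair; their
scores become the feature columns of a :class:`BaseScoreMatrix`. A
gradient-boosted LambdaMART ranker (lambdarank objective: pairwise
lambda gradients weighted by the |delta-NDCG| of swapping two candidates
within a query group) integrates the columns.

At desk scale a handful of query groups cannot support deep ensembles,
so the ranker boosts *corrections* on top of a warm start: the
per-group rank margins of a designated backbone base model (normally
the validation-best one). Rank margins make the warm start invariant to
strictly monotone rescaling of the backbone's scores, and the
piecewise-constant tree corrections preserve the backbone's ordering
wherever they are flat. The number of boosting rounds actually kept —
possibly zero — is the one maximizing validation NDCG, scanned with a
patience window; contribution weights are the per-column split gains of
the kept trees, normalized to sum to one (all weight on the backbone
when no tree is kept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lightgbm as lgb
import numpy as np
from scipy.stats import rankdata

from .data import RankingDataset
from .metrics import MetricFlag, ScoredLabeledList, grouped_metric

__all__ = [
    "BaseScoreMatrix",
    "RankerParams",
    "RankerModel",
    "select_top_models",
    "build_score_matrix",
    "filter_trainable_groups",
    "train_lambdamart",
    "contribution_weights",
]


@dataclass
class BaseScoreMatrix:
    """Per-pair base-model scores with relevance and grouping.

    rows follow pair order; columns follow ``model_names`` order.
    """

    pairs: list
    relevance: np.ndarray
    group_ids: np.ndarray
    scores: np.ndarray  # (n_pairs, n_models)
    model_names: tuple

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        self.relevance = np.asarray(self.relevance, int)
        self.group_ids = np.asarray(self.group_ids, object)
        self.model_names = tuple(self.model_names)
        n = len(self.pairs)
        if self.scores.shape != (n, len(self.model_names)):
            raise ValueError("score matrix shape must be (n_pairs, n_models)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score matrix must have no missing cells")
        if not np.all(np.isin(self.relevance, (0, 1))):
            raise ValueError("relevance must be binary")

    def restrict(self, mask: np.ndarray) -> "BaseScoreMatrix":
        return BaseScoreMatrix(
            [p for p, m in zip(self.pairs, mask) if m],
            self.relevance[mask],
            self.group_ids[mask],
            self.scores[mask],
            self.model_names,
        )

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.model_names.index(name)]


@dataclass(frozen=True)
class RankerParams:
    """LambdaMART settings, sized for desk-scale benchmarks."""

    n_trees: int = 100
    learning_rate: float = 0.1
    num_leaves: int = 15
    min_child_samples: int = 5
    ndcg_truncation: int = 10
    patience: int = 10
    init_margin_scale: float = 2.0


@dataclass
class RankerModel:
    """A fitted LambdaMART ensemble with its feature provenance."""

    booster: lgb.Booster
    model_names: tuple
    params: RankerParams
    seed: int
    init_model: str | None = None
    best_round: int | None = None

    def predict(self, matrix: BaseScoreMatrix) -> np.ndarray:
        if set(matrix.model_names) != set(self.model_names):
            raise ValueError("matrix provenance does not match the trained ranker")
        order = [matrix.model_names.index(m) for m in self.model_names]
        X = matrix.scores[:, order]
        pred = _init_margins(matrix, self.init_model, self.params.init_margin_scale)
        if self.best_round and self.best_round > 0:
            pred = pred + self.booster.predict(X, num_iteration=self.best_round)
        return pred


def select_top_models(validation_scores: dict, n: int) -> list:
    """Top-n model names by validation metric, descending.

    Ties break lexicographically by name; if fewer than n models exist,
    all are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not validation_scores:
        raise ValueError("no models to select from")
    ordered = sorted(validation_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [name for name, _ in ordered]
    if len(names) < n:
        warnings.warn(f"only {len(names)} model(s) available; requested top {n}")
        return names
    return names[:n]


def build_score_matrix(
    scorers: dict, dataset: RankingDataset, partition: str | list
) -> BaseScoreMatrix:
    """Score every labeled pair of the given partition(s) with every base model."""
    parts = [partition] if isinstance(partition, str) else list(partition)
    pairs, labels, gids = [], [], []
    for part in parts:
        p, y, g = dataset.pairs_in(part)
        pairs.extend(p)
        labels.append(y)
        gids.append(g)
    labels = np.concatenate(labels) if labels else np.zeros(0, int)
    gids = np.concatenate(gids) if gids else np.zeros(0, object)
    names = tuple(scorers)
    columns = [np.asarray(scorers[m].score_pairs(pairs, dataset.task)) for m in names]
    scores = np.column_stack(columns) if columns else np.zeros((0, 0))
    return BaseScoreMatrix(pairs, labels, gids, scores, names)


def filter_trainable_groups(matrix: BaseScoreMatrix) -> tuple:
    """Drop groups lacking both classes (no pairwise lambda is defined there).

    Returns (filtered matrix, number of dropped groups).
    """
    keep = np.ones(len(matrix.pairs), dtype=bool)
    dropped = 0
    for g in dict.fromkeys(matrix.group_ids):
        mask = matrix.group_ids == g
        rel = matrix.relevance[mask]
        if rel.sum() == 0 or rel.sum() == rel.size:
            keep &= ~mask
            dropped += 1
    return matrix.restrict(keep), dropped


def _group_sizes(group_ids: np.ndarray) -> list:
    sizes, last, count = [], None, 0
    for g in group_ids:
        if g != last and last is not None:
            sizes.append(count)
            count = 0
        last = g
        count += 1
    if count:
        sizes.append(count)
    return sizes


def _init_margins(matrix: BaseScoreMatrix, init_model: str | None, scale: float) -> np.ndarray:
    """Warm-start margins: per-group rank transform of the backbone column.

    Ranks are mapped to (-scale, scale); invariant to strictly monotone
    transforms of the backbone's scores. Zero margins when no backbone.
    """
    if init_model is None:
        return np.zeros(len(matrix.pairs))
    col = matrix.column(init_model)
    margins = np.zeros_like(col)
    for g in dict.fromkeys(matrix.group_ids):
        mask = matrix.group_ids == g
        r = rankdata(col[mask]) / (mask.sum() + 1.0)
        margins[mask] = scale * (2.0 * r - 1.0)
    return margins


def train_lambdamart(
    train_matrix: BaseScoreMatrix,
    valid_matrix: BaseScoreMatrix | None = None,
    params: RankerParams | None = None,
    seed: int = 0,
    init_model: str | None = None,
) -> RankerModel:
    """Fit the LambdaMART integrator on training groups.

    Every training group must contain both a positive and a negative
    candidate (otherwise no pairwise lambda is defined for it; see
    :func:`filter_trainable_groups`). Boosting runs for ``params.n_trees``
    rounds; the kept round count is the one with the best validation
    NDCG at ``params.ndcg_truncation``, scanning from round 0 (the bare
    warm start) and stopping after ``params.patience`` rounds without
    improvement. Without a validation matrix the scan uses the training
    groups.
    """
    params = params or RankerParams()
    if params.n_trees < 1:
        raise ValueError("tree count must be >= 1")
    if len(dict.fromkeys(train_matrix.group_ids)) < 2:
        raise ValueError("need at least 2 training groups")
    for g in dict.fromkeys(train_matrix.group_ids):
        rel = train_matrix.relevance[train_matrix.group_ids == g]
        if rel.sum() == 0 or rel.sum() == rel.size:
            raise ValueError(f"training group {g!r} lacks both classes")
    if init_model is not None and init_model not in train_matrix.model_names:
        raise ValueError(f"init model {init_model!r} not among base models")

    init_train = _init_margins(train_matrix, init_model, params.init_margin_scale)
    dtrain = lgb.Dataset(
        train_matrix.scores,
        label=train_matrix.relevance,
        group=_group_sizes(train_matrix.group_ids),
        init_score=init_train,
        params={"verbosity": -1},
        free_raw_data=False,
    )
    booster = lgb.train(
        {
            "objective": "lambdarank",
            "label_gain": [0, 1],
            "lambdarank_truncation_level": max(params.ndcg_truncation, 10),
            "num_leaves": params.num_leaves,
            "min_child_samples": params.min_child_samples,
            "learning_rate": params.learning_rate,
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": 1,
            "verbosity": -1,
            "seed": seed,
        },
        dtrain,
        num_boost_round=params.n_trees,
    )

    sel = valid_matrix if valid_matrix is not None and len(valid_matrix.pairs) else train_matrix
    sel_order = [sel.model_names.index(m) for m in train_matrix.model_names]
    sel_X = sel.scores[:, sel_order]
    sel_init = _init_margins(sel, init_model, params.init_margin_scale)
    flag = MetricFlag("ndcg", params.ndcg_truncation)

    def sel_value(pred: np.ndarray) -> float:
        data = ScoredLabeledList(pred, sel.relevance, groups=sel.group_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return grouped_metric(data, flag)

    best_round = 0
    best_value = sel_value(sel_init) if init_model is not None else -np.inf
    since_best = 0
    for r in range(1, params.n_trees + 1):
        value = sel_value(sel_init + booster.predict(sel_X, num_iteration=r))
        if value > best_value:
            best_round, best_value = r, value
            since_best = 0
        else:
            since_best += 1
            if since_best >= params.patience:
                break
    if best_round == 0 and init_model is None:
        best_round = 1  # keep at least one tree when there is no warm start
    return RankerModel(
        booster, train_matrix.model_names, params, seed, init_model, best_round
    )


def contribution_weights(ranker: RankerModel) -> dict:
    """Per-base-model contribution: normalized total split gain.

    Gains are accumulated over the kept boosting rounds. When no round
    is kept the ensemble is exactly the warm-start backbone, which then
    carries all the weight.
    """
    if ranker.booster is None:
        raise ValueError("ranker is not trained")
    names = ranker.model_names
    if not ranker.best_round:
        weights = np.zeros(len(names))
        weights[names.index(ranker.init_model)] = 1.0
    else:
        gains = np.asarray(
            ranker.booster.feature_importance(
                importance_type="gain", iteration=ranker.best_round
            ),
            float,
        )
        if gains.sum() <= 0:
            if ranker.init_model is not None:
                gains = np.zeros(len(names))
                gains[names.index(ranker.init_model)] = 1.0
            else:
                gains = np.ones(len(names))
        weights = gains / gains.sum()
    return dict(zip(names, weights.tolist()))
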