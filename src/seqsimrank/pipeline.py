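"""End-to-end run orchestration.

A run reads one or two embedding tables plus pair labels, builds the
grouped ranking dataset, trains the requested base models, selects the
top performers on validation, integrates them with the warm-started
LambdaMART ranker (fed out-of-fold base scores), evaluates everything
on the held-out test queries, and writes score tables, metric tables,
contribution weights and a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    PairLabelSet,
    RankingDataset,
    TaskSpec,
    build_ranking_dataset,
    read_embedding_table,
    read_pair_labels,
    write_score_table,
)
from .distribution import DISTRIBUTION_MODELS, train_distribution_model
from .interaction import INTERACTION_MODELS, train_interaction_model
from .ltr import (
    RankerParams,
    build_score_matrix,
    contribution_weights,
    filter_trainable_groups,
    select_top_models,
    train_lambdamart,
)
from .metrics import MetricFlag, ScoredLabeledList, grouped_metric, parse_metric_flag
from .representation import REPRESENTATION_MODELS, EncoderConfig, train_representation_model

logger = logging.getLogger("seqsimrank")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "evaluate_scores"]

#: CLI spellings for the neural architectures mapped to internal names
ARC_ALIASES = {
    "dssm": "dssm",
    "cdssm": "cdssm",
    "drmm": "drmm",
    "drmmtks": "drmm_tks",
    "drmm_tks": "drmm_tks",
    "match_lstm": "match_lstm",
    "duet": "duet",
    "knrm": "knrm",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    data_type: str  # homo | hetero
    bmk_vec: str | None = None  # homogeneous embedding table
    bmk_vec_a: str | None = None  # heterogeneous side-a table
    bmk_vec_b: str | None = None  # heterogeneous side-b table
    pos_label: str = "pos_label.txt"
    neg_label: str = "neg_label.txt"
    clf: tuple = ()
    arc: tuple = ()
    metric: str = "auc"
    gs_mode: int = 0
    seed: int = 0
    split: tuple = (0.6, 0.2, 0.2)
    top_n: int = 5
    layout: tuple | None = None  # (L, D) to declare matrix-layout tables
    out_dir: str = "seqsimrank_out"

    def __post_init__(self):
        if self.data_type not in ("homo", "hetero"):
            raise ValueError("data_type must be 'homo' or 'hetero'")
        if self.data_type == "homo":
            if not self.bmk_vec or self.bmk_vec_a or self.bmk_vec_b:
                raise ValueError("homogeneous runs need exactly one embedding table (bmk_vec)")
        else:
            if self.bmk_vec or not (self.bmk_vec_a and self.bmk_vec_b):
                raise ValueError(
                    "heterogeneous runs need two embedding tables (bmk_vec_a, bmk_vec_b)"
                )
        for name in self.clf:
            if name not in DISTRIBUTION_MODELS:
                raise ValueError(
                    f"unknown clf model {name!r}; valid: {', '.join(DISTRIBUTION_MODELS)}"
                )
        for name in self.arc:
            if name not in ARC_ALIASES:
                raise ValueError(
                    f"unknown arc model {name!r}; valid: {', '.join(sorted(set(ARC_ALIASES)))}"
                )
        if not self.clf and not self.arc:
            raise ValueError("at least one model (clf or arc) is required")
        parse_metric_flag(self.metric)  # validates the grammar


@dataclass
class ReportBundle:
    """Evaluation tables, score tables and provenance for one run."""

    config: RunConfig
    dataset: RankingDataset
    scorers: dict
    ranker: object
    weights: dict
    metric_table: pd.DataFrame
    test_scores: dict  # model name -> (pairs, scores)
    manifest: dict
    out_dir: Path


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, groups: np.ndarray, flags: list
) -> dict:
    """Evaluate one score column under several metric flags; infeasible
    metrics (e.g. roc@N with too few negatives) come back as NaN."""
    out = {}
    data = ScoredLabeledList(scores, labels, groups=groups)
    for flag in flags:
        try:
            out[str(flag)] = grouped_metric(data, flag)
        except ValueError:
            out[str(flag)] = float("nan")
    return out


def _metric_flags(run_flag: MetricFlag) -> list:
    flags = [MetricFlag("auc"), MetricFlag("aupr"), MetricFlag("ndcg", 10)]
    if str(run_flag) not in {str(f) for f in flags}:
        flags.append(run_flag)
    return flags


def _train_base_models(config: RunConfig, dataset: RankingDataset) -> dict:
    scorers = {}
    for name in config.clf:
        t0 = time.perf_counter()
        scorers[name] = train_distribution_model(
            name, dataset, gs_mode=config.gs_mode, metric=config.metric, seed=config.seed
        )
        logger.info("trained clf %s in %.1fs", name, time.perf_counter() - t0)
    for raw in config.arc:
        name = ARC_ALIASES[raw]
        t0 = time.perf_counter()
        if name in REPRESENTATION_MODELS:
            arch = "dssm_like" if name == "dssm" else "cdssm_like"
            cfg = EncoderConfig(architecture=arch, seed=config.seed)
            scorers[name] = train_representation_model(cfg, dataset, metric=config.metric)
        elif name in INTERACTION_MODELS:
            scorers[name] = train_interaction_model(
                name, dataset, seed=config.seed, metric=config.metric
            )
        logger.info("trained arc %s in %.1fs", name, time.perf_counter() - t0)
    return scorers


def _oof_train_matrix(scorers: dict, dataset: RankingDataset, n_folds: int, seed: int):
    """Out-of-fold base scores on the training partition.

    Each base model is refit (same hyperparameters) with one fold of
    training queries held out and scores that fold, so the LambdaMART
    integrator never sees a base model's in-sample scores.
    """
    from .ltr import BaseScoreMatrix

    train_queries = sorted(dataset.queries_in("train"))
    n_folds = min(n_folds, len(train_queries))
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(len(train_queries)), n_folds)
    pairs, labels, gids = dataset.pairs_in("train")
    names = tuple(scorers)
    oof = np.zeros((len(pairs), len(names)))
    qarr = np.asarray([q for q, _ in pairs], dtype=object)
    for fold in folds:
        held = {train_queries[i] for i in fold}
        mask = np.asarray([q in held for q in qarr])
        if not mask.any():
            continue
        partition = {
            q: ("heldout" if (p == "train" and q in held) else p)
            for q, p in dataset.partition.items()
        }
        sub = dataclasses.replace(dataset, partition=partition)
        held_pairs = [p for p, m in zip(pairs, mask) if m]
        for j, name in enumerate(names):
            refit = scorers[name].retrain(sub)
            oof[mask, j] = refit.score_pairs(held_pairs, dataset.task)
    return BaseScoreMatrix(pairs, labels, gids, oof, names)


def run_pipeline(config: RunConfig, task: TaskSpec | None = None, labels: PairLabelSet | None = None) -> ReportBundle:
    """Execute one full run: read, split, train, integrate, evaluate, write.

    ``task`` and ``labels`` may be passed directly (already in memory);
    otherwise they are read from the paths in the config. Deterministic
    given the config (including its seed).
    """
    t_start = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "status": "RUNNING",
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    manifest["status"] = f"FAILED at {name}: {exc}"
                    _write_json(out_dir / "manifest.json", manifest)
                return False

        return _Timer()

    try:
        with stage("read"):
            if task is None:
                if config.data_type == "homo":
                    corpus = read_embedding_table(config.bmk_vec, config.layout)
                    task = TaskSpec("homogeneous", corpus)
                else:
                    ca = read_embedding_table(config.bmk_vec_a, config.layout)
                    cb = read_embedding_table(config.bmk_vec_b, config.layout)
                    task = TaskSpec("heterogeneous", ca, cb)
            if labels is None:
                labels = read_pair_labels(config.pos_label, config.neg_label, task)

        with stage("split"):
            dataset = build_ranking_dataset(task, labels, config.split, config.seed)

        with stage("train_base"):
            scorers = _train_base_models(config, dataset)

        run_flag = parse_metric_flag(config.metric)
        flags = _metric_flags(run_flag)

        with stage("validate"):
            vpairs, vy, vg = dataset.pairs_in("valid")
            valid_values = {}
            for name, scorer in scorers.items():
                s = scorer.score_pairs(vpairs, task)
                valid_values[name] = grouped_metric(
                    ScoredLabeledList(s, vy, groups=vg), run_flag
                )
            top = select_top_models(valid_values, config.top_n)
            logger.info("validation %s: %s -> top %s", run_flag, valid_values, top)

        with stage("integrate"):
            top_scorers = {name: scorers[name] for name in top}
            train_matrix = _oof_train_matrix(top_scorers, dataset, 5, config.seed)
            train_matrix, dropped = filter_trainable_groups(train_matrix)
            if dropped:
                logger.info("dropped %d single-class training group(s) for LTR", dropped)
            valid_matrix, _ = filter_trainable_groups(
                build_score_matrix(top_scorers, dataset, "valid")
            )
            ndcg_k = run_flag.truncation if run_flag.name == "ndcg" and run_flag.truncation else 10
            params = RankerParams(ndcg_truncation=ndcg_k)
            init_model = top[0]  # validation-best backbone
            ranker = train_lambdamart(
                train_matrix, valid_matrix, params, config.seed, init_model=init_model
            )
            weights = contribution_weights(ranker)

        with stage("evaluate"):
            test_matrix = build_score_matrix(top_scorers, dataset, "test")
            rows = []
            test_scores = {}
            tpairs, ty, tg = dataset.pairs_in("test")
            for name in scorers:
                s = scorers[name].score_pairs(tpairs, task)
                test_scores[name] = (tpairs, s)
                rows.append({"model": name, **evaluate_scores(s, ty, tg, flags)})
            integrated = ranker.predict(test_matrix)
            test_scores["integrated"] = (test_matrix.pairs, integrated)
            rows.append(
                {
                    "model": "integrated",
                    **evaluate_scores(
                        integrated, test_matrix.relevance, test_matrix.group_ids, flags
                    ),
                }
            )
            metric_table = pd.DataFrame(rows).set_index("model")

        with stage("write"):
            for name, (pairs_, s) in test_scores.items():
                write_score_table(pairs_, s, out_dir / f"scores_{name}.tsv")
            metric_table.to_csv(out_dir / "metrics.tsv", sep="\t", float_format="%.10g")
            _write_json(out_dir / "metrics.json", _table_to_dict(metric_table))
            _write_json(out_dir / "contribution_weights.json", weights)
            manifest["validation_values"] = valid_values
            manifest["selected_models"] = top
            manifest["init_model"] = init_model
            manifest["kept_boosting_rounds"] = ranker.best_round
            manifest["partition_sizes"] = {
                part: len(dataset.queries_in(part)) for part in ("train", "valid", "test")
            }
            manifest["status"] = "OK"
            manifest["total_seconds"] = round(time.perf_counter() - t_start, 3)
            _write_json(out_dir / "manifest.json", manifest)
    except Exception:
        if manifest["status"] == "RUNNING":
            manifest["status"] = "FAILED"
            _write_json(out_dir / "manifest.json", manifest)
        raise

    return ReportBundle(
        config=config,
        dataset=dataset,
        scorers=scorers,
        ranker=ranker,
        weights=weights,
        metric_table=metric_table,
        test_scores=test_scores,
        manifest=manifest,
        out_dir=out_dir,
    )


def _table_to_dict(table: pd.DataFrame) -> dict:
    return {
        model: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
        for model, row in table.to_dict("index").items()
    }


def _write_json(path: Path, obj) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
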