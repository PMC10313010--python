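"""Ranking and retrieval performance measures.

All measures operate on binary relevance. Conventions:

* AUC — probability that a random positive outscores a random negative,
  with ties counted 1/2 (rank-sum estimator).
* AUPR — step-wise integral of the precision-recall curve over distinct
  score thresholds (no precision-envelope interpolation).
* ROC-n — area under the ROC curve truncated at the first ``n`` false
  positives, normalized by ``n * P`` so that perfect separation scores 1.
  The classic convention in remote-homology search (ROC50, ROC1).
* NDCG@k — gain ``2**rel - 1`` discounted by ``log2(rank + 1)``,
  normalized by the ideal ordering.
* Fmax / Smin — protein-centric function-annotation measures: the best
  harmonic mean of averaged precision/recall over score thresholds, and
  the minimal Euclidean combination of information-content-weighted
  remaining uncertainty and misinformation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ScoredLabeledList",
    "AnnotationSet",
    "MetricFlag",
    "curve_metrics",
    "auc_score",
    "aupr_score",
    "roc_n",
    "ndcg_at_k",
    "cafa_fmax",
    "cafa_smin",
    "roc_curve_points",
    "pr_curve_points",
    "parse_metric_flag",
    "grouped_metric",
]


@dataclass(frozen=True)
class ScoredLabeledList:
    """Scores with binary relevance labels, optionally grouped by query."""

    scores: np.ndarray
    labels: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))
        if self.groups is not None:
            groups = np.asarray(self.groups)
            if groups.shape != scores.shape:
                raise ValueError("groups must match scores in length")
            object.__setattr__(self, "groups", groups)


@dataclass
class AnnotationSet:
    """Per-protein term annotations for Fmax/Smin.

    truth: protein -> set of true terms (assumed already ontology-propagated).
    predictions: protein -> {term: score in [0, 1]}.
    information_content: term -> nonnegative IC in bits.
    """

    truth: Mapping[str, set]
    predictions: Mapping[str, Mapping[str, float]]
    information_content: Mapping[str, float] = field(default_factory=dict)


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both positive and negative labels are required")


def auc_score(scores, labels) -> float:
    """Rank-sum AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _require_both_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks resolve ties as 1/2
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr_score(scores, labels) -> float:
    """Area under the precision-recall curve via the step-wise integral."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _require_both_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # last index of each distinct-score block
    distinct = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    tp_t = tp[distinct].astype(float)
    fp_t = fp[distinct].astype(float)
    n_pos = float(labels.sum())
    recall = tp_t / n_pos
    precision = tp_t / (tp_t + fp_t)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def curve_metrics(data: ScoredLabeledList) -> dict:
    """AUC and AUPR for one scored list."""
    return {
        "auc": auc_score(data.scores, data.labels),
        "aupr": aupr_score(data.scores, data.labels),
    }


def roc_n(data: ScoredLabeledList, n: int) -> float:
    """Truncated ROC area (ROC-n), normalized so perfect ranking gives 1.

    Equal to the sum, over the first ``n`` false positives in descending
    score order, of the number of true positives ranked above each,
    divided by ``n * P``. Ties are broken by stable input order (warned).
    """
    scores = np.asarray(data.scores, dtype=float)
    labels = np.asarray(data.labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos < 1:
        raise ValueError("roc_n requires at least one positive")
    if n_neg < n:
        raise ValueError(
            f"roc_n requires at least n={n} negatives (got {n_neg}); use a smaller n"
        )
    if np.unique(scores).size < scores.size:
        warnings.warn("tied scores broken by stable input order in roc_n")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp_above = 0
    fp_seen = 0
    total = 0
    for rel in y:
        if rel == 1:
            tp_above += 1
        else:
            fp_seen += 1
            total += tp_above
            if fp_seen == n:
                break
    return float(total) / (n * n_pos)


def ndcg_at_k(relevance: Sequence[int], k: int | None = None) -> float:
    """NDCG of binary relevance labels listed in predicted order."""
    rel = np.asarray(relevance, dtype=float)
    if rel.size == 0 or rel.sum() == 0:
        raise ValueError("NDCG undefined: no positive relevance in ranking")
    if k is None:
        k = rel.size
    discounts = 1.0 / np.log2(np.arange(2, rel.size + 2))
    gains = 2.0 ** rel - 1.0
    dcg = float(np.sum((gains * discounts)[:k]))
    ideal = np.sort(rel)[::-1]
    idcg = float(np.sum(((2.0 ** ideal - 1.0) * discounts)[:k]))
    return dcg / idcg


def cafa_fmax(annotations: AnnotationSet) -> dict:
    """Protein-centric Fmax over score thresholds.

    At each threshold t (swept over the distinct predicted scores),
    precision is averaged over proteins with at least one prediction at or
    above t, recall over all proteins with nonempty truth. The smallest
    maximizing threshold is reported on ties.
    """
    proteins = [p for p, terms in annotations.truth.items() if terms]
    if not proteins:
        raise ValueError("Fmax undefined: empty truth for every protein")
    thresholds = sorted(
        {s for preds in annotations.predictions.values() for s in preds.values()}
    )
    best_f, best_t = 0.0, None
    any_threshold_valid = False
    for t in thresholds:
        precisions, recalls = [], []
        for p in proteins:
            truth = annotations.truth[p]
            pred_at_t = {
                term
                for term, s in annotations.predictions.get(p, {}).items()
                if s >= t
            }
            if pred_at_t:
                precisions.append(len(pred_at_t & truth) / len(pred_at_t))
            recalls.append(len(pred_at_t & truth) / len(truth))
        if not precisions:
            continue
        any_threshold_valid = True
        pr = float(np.mean(precisions))
        rc = float(np.mean(recalls))
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        # ascending sweep: strict improvement keeps the smallest tied t
        if best_t is None or f > best_f:
            best_f, best_t = f, t
    if not any_threshold_valid:
        warnings.warn("no threshold admits any prediction; Fmax reported as 0")
        return {"fmax": 0.0, "best_threshold": None}
    if best_t is None and thresholds:
        best_t = thresholds[0]
    return {"fmax": best_f, "best_threshold": best_t}


def cafa_smin(annotations: AnnotationSet) -> float:
    """Minimum semantic distance S(t) = sqrt(ru(t)^2 + mi(t)^2).

    ru(t): average (over proteins) total IC of true terms missed at t.
    mi(t): average total IC of false terms predicted at t.
    """
    proteins = [p for p, terms in annotations.truth.items() if terms]
    if not proteins:
        raise ValueError("Smin undefined: empty truth for every protein")
    ic = annotations.information_content
    used_terms = set()
    for p in proteins:
        used_terms |= set(annotations.truth[p])
        used_terms |= set(annotations.predictions.get(p, {}))
    for term in sorted(used_terms):
        if term not in ic:
            raise KeyError(f"information content missing for term {term!r}")
    thresholds = sorted(
        {s for preds in annotations.predictions.values() for s in preds.values()}
    )
    # a threshold above every score (empty prediction set) is always available
    candidate_ts = list(thresholds) + [np.inf]
    best = np.inf
    for t in candidate_ts:
        ru_total = 0.0
        mi_total = 0.0
        for p in proteins:
            truth = annotations.truth[p]
            pred_at_t = {
                term
                for term, s in annotations.predictions.get(p, {}).items()
                if s >= t
            }
            ru_total += sum(ic[term] for term in truth - pred_at_t)
            mi_total += sum(ic[term] for term in pred_at_t - truth)
        ru = ru_total / len(proteins)
        mi = mi_total / len(proteins)
        best = min(best, float(np.hypot(ru, mi)))
    return best


def roc_curve_points(data: ScoredLabeledList) -> np.ndarray:
    """(FPR, TPR) coordinates of the ROC curve, descending-score order."""
    order = np.argsort(-data.scores, kind="stable")
    y = data.labels[order]
    tp = np.concatenate([[0], np.cumsum(y)])
    fp = np.concatenate([[0], np.cumsum(1 - y)])
    return np.column_stack([fp / max(fp[-1], 1), tp / max(tp[-1], 1)])


def pr_curve_points(data: ScoredLabeledList) -> np.ndarray:
    """(recall, precision) coordinates over distinct thresholds."""
    order = np.argsort(-data.scores, kind="stable")
    s = data.scores[order]
    y = data.labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    distinct = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    n_pos = max(int(data.labels.sum()), 1)
    recall = tp[distinct] / n_pos
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    return np.column_stack([recall, precision])


@dataclass(frozen=True)
class MetricFlag:
    """Parsed form of a -metric flag, e.g. auc, roc@50, ndcg@10."""

    name: str
    truncation: int | None = None

    def __str__(self) -> str:
        return self.name if self.truncation is None else f"{self.name}@{self.truncation}"


_METRIC_RE = re.compile(r"^(auc|aupr|roc|ndcg|fmax|smin)(?:@(\d+))?$")


def parse_metric_flag(flag: str) -> MetricFlag:
    """Parse the metric grammar: auc | aupr | roc@N | ndcg[@N] | fmax | smin."""
    m = _METRIC_RE.match(flag.strip().lower())
    if not m:
        raise ValueError(f"unknown metric flag {flag!r}")
    name, trunc = m.group(1), m.group(2)
    if name == "roc" and trunc is None:
        raise ValueError("roc requires a truncation, e.g. roc@50")
    if trunc is not None and name in ("auc", "aupr", "fmax", "smin"):
        raise ValueError(f"metric {name!r} takes no truncation")
    return MetricFlag(name, int(trunc) if trunc is not None else None)


def grouped_metric(data: ScoredLabeledList, flag: MetricFlag) -> float:
    """Evaluate a parsed metric flag on a (possibly grouped) scored list.

    auc / aupr / roc@N pool all pairs; ndcg averages per-group NDCG over
    groups that contain at least one positive (groups without positives
    are skipped with a warning, as NDCG has zero ideal gain there).
    """
    if flag.name in ("auc", "aupr", "roc"):
        if flag.name == "auc":
            return auc_score(data.scores, data.labels)
        if flag.name == "aupr":
            return aupr_score(data.scores, data.labels)
        return roc_n(data, flag.truncation)
    if flag.name == "ndcg":
        if data.groups is None:
            order = np.argsort(-data.scores, kind="stable")
            return ndcg_at_k(data.labels[order], flag.truncation)
        values = []
        skipped = 0
        for g in np.unique(data.groups):
            mask = data.groups == g
            labels = data.labels[mask]
            if labels.sum() == 0:
                skipped += 1
                continue
            order = np.argsort(-data.scores[mask], kind="stable")
            values.append(ndcg_at_k(labels[order], flag.truncation))
        if skipped:
            warnings.warn(f"{skipped} group(s) without positives skipped for NDCG")
        if not values:
            raise ValueError("no group with a positive label; NDCG undefined")
        return float(np.mean(values))
    raise ValueError(f"metric {flag.name!r} needs an AnnotationSet, not a scored list")
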