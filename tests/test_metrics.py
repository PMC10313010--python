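"""Metric implementations against hand computations and brute-force oracles."""

import numpy as np
import pytest

from seqsimrank.metrics import (
    AnnotationSet,
    MetricFlag,
    ScoredLabeledList,
    auc_score,
    aupr_score,
    cafa_fmax,
    cafa_smin,
    curve_metrics,
    grouped_metric,
    ndcg_at_k,
    parse_metric_flag,
    roc_n,
)

from _oracles import brute_auc, brute_aupr, brute_fmax, brute_ndcg, brute_roc_n, brute_smin

# ---------------------------------------------------------------------------
# hand-worked cases


def test_auc_aupr_hand_cases():
    out = curve_metrics(ScoredLabeledList([0.9, 0.1], [1, 0]))
    assert out == {"auc": 1.0, "aupr": 1.0}
    # 1 concordant pair of the 4 pos x neg pairs
    assert auc_score([0.2, 0.8, 0.6, 0.4], [1, 0, 1, 0]) == 0.25
    assert auc_score([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([5, 4, 3, 2, 1], [1, 1, 0, 0, 0], 1.0),  # all positives precede first FP
        ([3, 2, 1], [0, 1, 1], 0.0),  # no positive above the only counted FP
        ([3, 2, 1], [1, 0, 1], 0.5),  # one of two positives above the first FP
    ],
)
def test_roc1_hand_cases(scores, labels, expected):
    assert roc_n(ScoredLabeledList(scores, labels), 1) == expected


def test_ndcg_hand_cases():
    assert ndcg_at_k([1, 0], 2) == 1.0
    assert ndcg_at_k([0, 1], 2) == pytest.approx(1 / np.log2(3), abs=1e-12)
    assert ndcg_at_k([0, 1], 1) == 0.0


def test_fmax_hand_case():
    ann = AnnotationSet(
        truth={"p": {"A", "B"}},
        predictions={"p": {"A": 0.9, "C": 0.6}},
    )
    out = cafa_fmax(ann)
    assert out["fmax"] == pytest.approx(2 / 3, abs=1e-12)
    assert out["best_threshold"] == pytest.approx(0.9)
    perfect = cafa_fmax(
        AnnotationSet(truth={"p": {"A"}}, predictions={"p": {"A": 1.0}})
    )
    assert perfect["fmax"] == 1.0


def test_smin_hand_cases():
    ann = AnnotationSet(
        truth={"p": {"A", "B"}},
        predictions={"p": {"A": 1.0}},
        information_content={"A": 1.0, "B": 2.0},
    )
    assert cafa_smin(ann) == pytest.approx(2.0, abs=1e-12)
    # a low-scored false term is excluded by a higher threshold: smin = 0
    ann2 = AnnotationSet(
        truth={"p": {"A", "B"}},
        predictions={"p": {"A": 1.0, "B": 1.0, "C": 0.4}},
        information_content={"A": 1.0, "B": 2.0, "C": 3.0},
    )
    assert cafa_smin(ann2) == 0.0
    perfect = AnnotationSet(
        truth={"p": {"A"}}, predictions={"p": {"A": 1.0}}, information_content={"A": 5.0}
    )
    assert cafa_smin(perfect) == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence on random instances


def _random_scored(rng, n):
    scores = rng.random(n)
    if rng.random() < 0.4:  # exercise tie handling
        scores = np.round(scores, 1)
    labels = np.zeros(n, int)
    labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
    return scores, labels


def test_rank_metrics_match_brute_force_oracles(rng):
    for _ in range(220):
        n = int(rng.integers(4, 31))
        scores, labels = _random_scored(rng, n)
        if labels.sum() in (0, n):
            continue
        assert auc_score(scores, labels) == pytest.approx(
            brute_auc(scores, labels), abs=1e-12
        )
        assert aupr_score(scores, labels) == pytest.approx(
            brute_aupr(list(scores), list(labels)), abs=1e-12
        )
        n_neg = int(n - labels.sum())
        m = int(rng.integers(1, n_neg + 1))
        if len(set(scores)) == len(scores):  # stable-order tie rule matches brute sort
            data = ScoredLabeledList(scores, labels)
            assert roc_n(data, m) == pytest.approx(
                brute_roc_n(list(scores), list(labels), m), abs=1e-12
            )
        order = np.argsort(-scores, kind="stable")
        k = int(rng.integers(1, n + 1))
        assert ndcg_at_k(labels[order], k) == pytest.approx(
            brute_ndcg(list(labels[order]), k), abs=1e-12
        )


def test_annotation_metrics_match_brute_force_oracles(rng):
    terms = [f"t{i}" for i in range(8)]
    for _ in range(200):
        n_prot = int(rng.integers(1, 6))
        truth, predictions, ic = {}, {}, {t: float(rng.random() * 4 + 0.1) for t in terms}
        for i in range(n_prot):
            p = f"p{i}"
            truth[p] = set(rng.choice(terms, size=rng.integers(1, 5), replace=False))
            pred_terms = rng.choice(terms, size=rng.integers(0, 6), replace=False)
            predictions[p] = {t: float(np.round(rng.random(), 2)) for t in pred_terms}
        if not any(predictions.values()):
            continue
        ann = AnnotationSet(truth, predictions, ic)
        assert cafa_fmax(ann)["fmax"] == pytest.approx(
            brute_fmax(truth, predictions), abs=1e-12
        )
        assert cafa_smin(ann) == pytest.approx(
            brute_smin(truth, predictions, ic), abs=1e-12
        )


# ---------------------------------------------------------------------------
# invariants


def test_auc_complement_under_score_negation(rng):
    for _ in range(50):
        n = int(rng.integers(4, 30))
        scores = rng.normal(size=n)  # continuous: ties a.s. absent
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        assert auc_score(scores, labels) + auc_score(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )


def test_roc_n_with_all_negatives_equals_auc(rng):
    for _ in range(50):
        n = int(rng.integers(4, 30))
        scores = rng.normal(size=n)
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n - 1), replace=False)] = 1
        n_neg = int(n - labels.sum())
        data = ScoredLabeledList(scores, labels)
        assert roc_n(data, n_neg) == pytest.approx(auc_score(scores, labels), abs=1e-12)


def test_ndcg_depends_only_on_order(rng):
    labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
    scores = rng.random(len(labels))
    order = np.argsort(-scores, kind="stable")
    base = ndcg_at_k(labels[order], 4)
    transformed = np.exp(5 * scores) + 3  # strictly monotone transform
    order2 = np.argsort(-transformed, kind="stable")
    assert ndcg_at_k(labels[order2], 4) == base


# ---------------------------------------------------------------------------
# error handling and the metric-flag grammar


def test_single_class_inputs_rejected():
    with pytest.raises(ValueError):
        auc_score([0.1, 0.2], [1, 1])
    with pytest.raises(ValueError):
        ndcg_at_k([0, 0, 0])
    with pytest.raises(ValueError):
        roc_n(ScoredLabeledList([0.5, 0.6], [1, 0]), 2)  # only one negative


def test_smin_requires_information_content():
    ann = AnnotationSet(
        truth={"p": {"A"}}, predictions={"p": {"B": 0.5}}, information_content={"A": 1.0}
    )
    with pytest.raises(KeyError, match="B"):
        cafa_smin(ann)


@pytest.mark.parametrize(
    "flag, name, trunc",
    [("auc", "auc", None), ("roc@50", "roc", 50), ("ndcg@10", "ndcg", 10), ("ndcg", "ndcg", None), ("fmax", "fmax", None)],
)
def test_metric_flag_grammar(flag, name, trunc):
    parsed = parse_metric_flag(flag)
    assert (parsed.name, parsed.truncation) == (name, trunc)


@pytest.mark.parametrize("bad", ["roc", "auc@5", "accuracy", "ndcg@", "smin@2"])
def test_metric_flag_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_metric_flag(bad)


def test_grouped_ndcg_skips_positive_free_groups():
    data = ScoredLabeledList(
        [0.9, 0.1, 0.8, 0.2], [1, 0, 0, 0], groups=np.array(["a", "a", "b", "b"])
    )
    with pytest.warns(UserWarning, match="without positives"):
        value = grouped_metric(data, MetricFlag("ndcg", 10))
    assert value == 1.0  # only group a counts, and it is perfectly ranked
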