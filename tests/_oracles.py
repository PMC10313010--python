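"""Naive brute-force reference implementations used as metric oracles.

Deliberately simple and structurally independent of the package code:
exhaustive pair counting, explicit threshold re-scans, direct formulas.
"""

import numpy as np


def brute_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_aupr(scores, labels):
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_roc_n(scores, labels, n):
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp_above, fp_seen, total = 0, 0, 0
    for i in order:
        if labels[i] == 1:
            tp_above += 1
        else:
            fp_seen += 1
            total += tp_above
            if fp_seen == n:
                break
    return total / (n * sum(labels))


def brute_ndcg(rel_in_order, k):
    def dcg(rel):
        return sum((2**r - 1) / np.log2(i + 2) for i, r in enumerate(rel[:k]))

    return dcg(list(rel_in_order)) / dcg(sorted(rel_in_order, reverse=True))


def brute_fmax(truth, predictions):
    thresholds = sorted({s for preds in predictions.values() for s in preds.values()})
    best = 0.0
    proteins = [p for p in truth if truth[p]]
    for t in thresholds:
        precisions, recalls = [], []
        for p in proteins:
            pred = {term for term, s in predictions.get(p, {}).items() if s >= t}
            if pred:
                precisions.append(len(pred & truth[p]) / len(pred))
            recalls.append(len(pred & truth[p]) / len(truth[p]))
        if not precisions:
            continue
        pr = sum(precisions) / len(precisions)
        rc = sum(recalls) / len(recalls)
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def brute_smin(truth, predictions, ic):
    thresholds = sorted({s for preds in predictions.values() for s in preds.values()})
    thresholds.append(float("inf"))
    proteins = [p for p in truth if truth[p]]
    best = float("inf")
    for t in thresholds:
        ru = mi = 0.0
        for p in proteins:
            pred = {term for term, s in predictions.get(p, {}).items() if s >= t}
            ru += sum(ic[x] for x in truth[p] - pred)
            mi += sum(ic[x] for x in pred - truth[p])
        ru /= len(proteins)
        mi /= len(proteins)
        best = min(best, (ru**2 + mi**2) ** 0.5)
    return best


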