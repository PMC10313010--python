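"""Embedding tables, pair labels, and grouped ranking datasets.

The on-disk embedding table format is tab-separated text:
column 1 is the item identifier, the remaining columns are decimal
floats. An optional first line ``#shape L D`` switches to matrix layout,
in which case each row's ``L*D`` values are reshaped row-major into an
``L x D`` per-token matrix. Pair-label files are two-column whitespace-
separated text, one ``query_id candidate_id`` pair per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "EmbeddedCorpus",
    "PairLabelSet",
    "TaskSpec",
    "RankingDataset",
    "FormatError",
    "read_embedding_table",
    "write_embedding_table",
    "read_pair_labels",
    "write_pair_labels",
    "build_ranking_dataset",
    "write_score_table",
]


class FormatError(ValueError):
    """Malformed input table (bad row width, duplicate id, non-numeric field)."""


@dataclass(frozen=True)
class EmbeddedCorpus:
    """Identifier-indexed table of dense embeddings.

    values has shape (n, D) for vector layout or (n, L, D) for matrix
    (per-token) layout. Identifiers are unique and ordered.
    """

    ids: tuple
    values: np.ndarray
    layout: Literal["vector", "matrix"] = "vector"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        ids = tuple(str(i) for i in self.ids)
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate identifiers in corpus")
        if not ids:
            raise ValueError("corpus must contain at least one item")
        expected_ndim = 2 if self.layout == "vector" else 3
        if values.ndim != expected_ndim or values.shape[0] != len(ids):
            raise ValueError(
                f"{self.layout} layout requires values of ndim {expected_ndim} "
                f"with one row per id"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("embeddings must be finite")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "_index", {item: k for k, item in enumerate(ids)}
        )

    @property
    def dim(self) -> int:
        return int(self.values.shape[-1])

    @property
    def shape(self) -> tuple:
        return tuple(self.values.shape[1:])

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, item: str) -> np.ndarray:
        try:
            return self.values[self._index[item]]
        except KeyError:
            raise KeyError(f"identifier {item!r} not in corpus") from None

    def take(self, items: Sequence[str]) -> np.ndarray:
        return self.values[[self._index[i] for i in items]]


@dataclass(frozen=True)
class TaskSpec:
    """Homogeneous (one corpus) or heterogeneous (two corpora) task."""

    kind: Literal["homogeneous", "heterogeneous"]
    corpus_a: EmbeddedCorpus
    corpus_b: EmbeddedCorpus | None = None

    def __post_init__(self):
        if self.kind == "homogeneous" and self.corpus_b is not None:
            raise ValueError("homogeneous tasks reference exactly one corpus")
        if self.kind == "heterogeneous" and self.corpus_b is None:
            raise ValueError("heterogeneous tasks reference exactly two corpora")

    @property
    def query_corpus(self) -> EmbeddedCorpus:
        return self.corpus_a

    @property
    def candidate_corpus(self) -> EmbeddedCorpus:
        return self.corpus_b if self.corpus_b is not None else self.corpus_a

    def resolve(self, pair: tuple) -> tuple:
        q, c = pair
        return self.query_corpus.get(q), self.candidate_corpus.get(c)


def _canonical(pair: tuple) -> tuple:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairLabelSet:
    """Known positive and negative (query, candidate) identifier pairs."""

    positives: tuple
    negatives: tuple

    def __post_init__(self):
        pos = tuple((str(a), str(b)) for a, b in self.positives)
        neg = tuple((str(a), str(b)) for a, b in self.negatives)
        if len(set(pos)) != len(pos) or len(set(neg)) != len(neg):
            raise ValueError("duplicate pairs within a label list")
        overlap = set(pos) & set(neg)
        if overlap:
            raise ValueError(f"pairs labeled both positive and negative: {sorted(overlap)[:5]}")
        object.__setattr__(self, "positives", pos)
        object.__setattr__(self, "negatives", neg)

    @property
    def queries(self) -> tuple:
        seen = dict.fromkeys(q for q, _ in self.positives + self.negatives)
        return tuple(seen)

    def all_pairs(self) -> list:
        return list(self.positives) + list(self.negatives)

    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positives), int), np.zeros(len(self.negatives), int)]
        )


@dataclass(frozen=True)
class RankingDataset:
    """Per-query candidate groups with binary relevance and a partition.

    groups: query_id -> list of (candidate_id, relevance) with relevance
    in {0, 1}. partition: query_id -> 'train' | 'valid' | 'test'.
    """

    groups: dict
    partition: dict
    task: TaskSpec
    seed: int

    def queries_in(self, part: str) -> list:
        return [q for q, p in self.partition.items() if p == part]

    def pairs_in(self, part: str):
        """(query, candidate) pairs, labels, and group ids of one partition."""
        pairs, labels, gids = [], [], []
        for q in self.queries_in(part):
            for cand, rel in self.groups[q]:
                pairs.append((q, cand))
                labels.append(rel)
                gids.append(q)
        return pairs, np.asarray(labels, int), np.asarray(gids, object)


# ---------------------------------------------------------------------------
# embedding tables


def read_embedding_table(path, layout: tuple | None = None) -> EmbeddedCorpus:
    """Read an embedding table.

    layout: None for vector layout, or (L, D) for matrix layout. A
    ``#shape L D`` header line in the file also selects matrix layout
    (an explicit argument must agree with the header).
    """
    path = Path(path)
    header_shape = None
    ids, rows = [], []
    seen = set()
    width = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#shape"):
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: malformed #shape header")
                header_shape = (int(parts[1]), int(parts[2]))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: row needs an id and at least one value")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise FormatError(
                    f"{path}:{lineno}: inconsistent row width "
                    f"({len(fields)} fields, expected {width})"
                )
            ident = fields[0]
            if ident in seen:
                raise FormatError(f"{path}:{lineno}: duplicate identifier {ident!r}")
            seen.add(ident)
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            ids.append(ident)
    if not ids:
        raise FormatError(f"{path}: empty embedding table")
    shape = layout if layout is not None else header_shape
    if header_shape is not None and layout is not None and tuple(layout) != header_shape:
        raise FormatError(
            f"{path}: declared layout {tuple(layout)} conflicts with header {header_shape}"
        )
    values = np.asarray(rows, dtype=float)
    if shape is None:
        return EmbeddedCorpus(tuple(ids), values, layout="vector")
    L, D = shape
    if values.shape[1] != L * D:
        raise FormatError(
            f"{path}: row width {values.shape[1]} not compatible with shape {L}x{D}"
        )
    return EmbeddedCorpus(tuple(ids), values.reshape(len(ids), L, D), layout="matrix")


def write_embedding_table(corpus: EmbeddedCorpus, path) -> None:
    """Write a corpus in the embedding table format (round-trips exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if corpus.layout == "matrix":
            L, D = corpus.shape
            fh.write(f"#shape {L} {D}\n")
        flat = corpus.values.reshape(len(corpus), -1)
        for ident, row in zip(corpus.ids, flat):
            fh.write(ident + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Pair labels


def _read_pair_file(path) -> list:
    pairs = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two whitespace-separated identifiers"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def read_pair_labels(pos_path, neg_path, task: TaskSpec) -> PairLabelSet:
    """Read positive/negative pair files and validate ids against the task.

    For homogeneous tasks each pair is canonicalized to (min, max) id
    order before duplicate checks, so (a, b) and (b, a) are one pair.
    """
    raw_pos = _read_pair_file(pos_path)
    raw_neg = _read_pair_file(neg_path)

    missing = []
    for q, c in raw_pos + raw_neg:
        if q not in task.query_corpus:
            missing.append(q)
        if c not in task.candidate_corpus:
            missing.append(c)
    if missing:
        raise KeyError(
            "pair identifiers not present in the task's corpora: "
            + ", ".join(sorted(set(missing)))
        )

    def dedup(pairs: Iterable[tuple], which: str) -> list:
        out, seen = [], set()
        dups = 0
        for p in pairs:
            key = _canonical(p) if task.kind == "homogeneous" else p
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            out.append(key)
        if dups:
            warnings.warn(f"{dups} duplicate {which} pair(s) collapsed after canonicalization")
        return out

    pos = dedup(raw_pos, "positive")
    neg = dedup(raw_neg, "negative")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(
            f"pairs present in both label files: {sorted(overlap)[:5]}"
        )
    return PairLabelSet(tuple(pos), tuple(neg))


def write_pair_labels(labels: PairLabelSet, pos_path, neg_path) -> None:
    for path, pairs in ((pos_path, labels.positives), (neg_path, labels.negatives)):
        with Path(path).open("w", encoding="utf-8") as fh:
            for q, c in pairs:
                fh.write(f"{q} {c}\n")


def write_score_table(pairs: Sequence[tuple], scores: Sequence[float], path) -> None:
    """Three-column TSV: query_id, candidate_id, score."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for (q, c), s in zip(pairs, scores):
            fh.write(f"{q}\t{c}\t{s:.10g}\n")


# ---------------------------------------------------------------------------
# Ranking dataset assembly


def build_ranking_dataset(
    task: TaskSpec,
    labels: PairLabelSet,
    split: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> RankingDataset:
    """Group labeled candidates by query and partition at the query level.

    Queries (never individual pairs) are shuffled with the seed and dealt
    into train/valid/test, so no query's candidates straddle partitions.
    The assignment depends only on the query-id set, fractions, and seed.

    For homogeneous tasks every *item* is a potential query and a
    potential candidate, so the split is item-level: both members of a
    pair must share a partition, and pairs straddling two partitions are
    dropped (with a warning). Keeping them would let item-memorizing
    models see test items during training.
    """
    if abs(sum(split) - 1.0) > 1e-9 or len(split) != 3:
        raise ValueError("split must be three fractions summing to 1")

    def assign(units: list) -> dict:
        if len(units) < 3:
            raise ValueError("need at least 3 distinct queries to partition")
        rng = np.random.default_rng(seed)
        shuffled = [units[i] for i in rng.permutation(len(units))]
        n_train = int(round(split[0] * len(units)))
        n_valid = int(round(split[1] * len(units)))
        parts = {
            "train": shuffled[:n_train],
            "valid": shuffled[n_train : n_train + n_valid],
            "test": shuffled[n_train + n_valid :],
        }
        for name, members in parts.items():
            if not members:
                raise ValueError(
                    f"partition {name!r} received zero queries; "
                    "provide more queries or different fractions"
                )
        return {u: name for name, members in parts.items() for u in members}

    all_pairs = list(zip(labels.all_pairs(), labels.labels()))
    if task.kind == "homogeneous":
        items = sorted({x for (a, b), _ in all_pairs for x in (a, b)})
        partition = assign(items)
        kept, dropped = [], 0
        for (a, b), rel in all_pairs:
            if partition[a] == partition[b]:
                kept.append(((a, b), rel))
            else:
                dropped += 1
        if dropped:
            warnings.warn(
                f"{dropped} cross-partition pair(s) dropped by the item-level split"
            )
        groups: dict = {}
        for (q, c), rel in kept:
            groups.setdefault(q, []).append((c, int(rel)))
        partition = {q: partition[q] for q in groups}
    else:
        groups = {}
        for (q, c), rel in all_pairs:
            groups.setdefault(q, []).append((c, int(rel)))
        partition = assign(sorted(groups))
    # candidate order within a group is sorted by id so that tied scores are
    # broken by an order uncorrelated with the labels
    groups = {q: sorted(cands) for q, cands in groups.items()}
    return RankingDataset(groups=groups, partition=partition, task=task, seed=seed)
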