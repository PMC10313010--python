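"""Embedding-table and pair-label I/O, and ranking-dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqsimrank.data import (
    EmbeddedCorpus,
    FormatError,
    PairLabelSet,
    TaskSpec,
    build_ranking_dataset,
    read_embedding_table,
    read_pair_labels,
    write_embedding_table,
    write_pair_labels,
)


def corpus_of(ids, values, layout="vector"):
    return EmbeddedCorpus(tuple(ids), np.asarray(values, float), layout=layout)


class TestEmbeddingTable:
    def test_single_row_vector_parse(self, tmp_path):
        path = tmp_path / "v.txt"
        path.write_text("s1\t0.1\t0.2\n")
        corpus = read_embedding_table(path)
        assert corpus.ids == ("s1",)
        assert corpus.layout == "vector"
        assert corpus.dim == 2
        np.testing.assert_array_equal(corpus.get("s1"), [0.1, 0.2])

    def test_inconsistent_row_width_names_offending_line(self, tmp_path):
        path = tmp_path / "v.txt"
        path.write_text("a\t1\t2\t3\t4\nb\t1\t2\t3\n")
        with pytest.raises(FormatError, match=":2"):
            read_embedding_table(path)

    def test_matrix_layout_row_major_reshape(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("s1\t1\t2\t3\t4\n")
        corpus = read_embedding_table(path, layout=(2, 2))
        assert corpus.layout == "matrix"
        np.testing.assert_array_equal(corpus.get("s1"), [[1, 2], [3, 4]])

    def test_shape_header_selects_matrix_layout(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("#shape 2 3\ns1\t1\t2\t3\t4\t5\t6\n")
        corpus = read_embedding_table(path)
        assert corpus.shape == (2, 3)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("a\t1\t2\na\t3\t4\n", "duplicate"),
            ("a\t1\tx\n", "non-numeric"),
            ("a\t1\t2\t3\n", "not compatible"),
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, content, match):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        layout = (2, 2) if "compatible" in match else None
        with pytest.raises(FormatError, match=match):
            read_embedding_table(path, layout=layout)

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(1, 6),
        d=st.integers(1, 5),
        matrix=st.booleans(),
        data=st.data(),
    )
    def test_round_trip_preserves_everything(self, tmp_path_factory, n, d, matrix, data):
        values = data.draw(
            st.lists(
                st.lists(
                    st.floats(-1e12, 1e12, allow_nan=False, width=64),
                    min_size=d * (3 if matrix else 1),
                    max_size=d * (3 if matrix else 1),
                ),
                min_size=n,
                max_size=n,
            )
        )
        arr = np.asarray(values)
        if matrix:
            arr = arr.reshape(n, 3, d)
        corpus = corpus_of(
            [f"id{i}" for i in range(n)], arr, layout="matrix" if matrix else "vector"
        )
        path = tmp_path_factory.mktemp("rt") / "table.txt"
        write_embedding_table(corpus, path)
        back = read_embedding_table(path)
        assert back.ids == corpus.ids
        assert back.layout == corpus.layout
        np.testing.assert_array_equal(back.values, corpus.values)


class TestPairLabels:
    @pytest.fixture()
    def task(self):
        ids = ["q1", "d3", "d5", "a", "b"]
        return TaskSpec("homogeneous", corpus_of(ids, np.eye(5)))

    def write(self, tmp_path, pos, neg):
        p, n = tmp_path / "pos.txt", tmp_path / "neg.txt"
        p.write_text("".join(f"{a} {b}\n" for a, b in pos))
        n.write_text("".join(f"{a} {b}\n" for a, b in neg))
        return p, n

    def test_basic_read(self, tmp_path, task):
        p, n = self.write(tmp_path, [("q1", "d3")], [("q1", "d5")])
        labels = read_pair_labels(p, n, task)
        assert len(labels.positives) == 1 and len(labels.negatives) == 1

    def test_pair_in_both_files_conflicts(self, tmp_path, task):
        p, n = self.write(tmp_path, [("q1", "d3")], [("q1", "d3")])
        with pytest.raises(ValueError, match="both"):
            read_pair_labels(p, n, task)

    def test_homogeneous_orientation_canonicalized(self, tmp_path, task):
        p, n = self.write(tmp_path, [("a", "b"), ("b", "a")], [("q1", "d5")])
        with pytest.warns(UserWarning, match="duplicate"):
            labels = read_pair_labels(p, n, task)
        assert labels.positives == (("a", "b"),)

    def test_reversing_all_pairs_gives_identical_set(self, tmp_path, task):
        p, n = self.write(tmp_path, [("a", "b"), ("q1", "d3")], [("q1", "d5")])
        labels = read_pair_labels(p, n, task)
        p2, n2 = self.write(tmp_path, [("b", "a"), ("d3", "q1")], [("d5", "q1")])
        reversed_labels = read_pair_labels(p2, n2, task)
        assert labels == reversed_labels

    def test_unresolvable_ids_listed(self, tmp_path, task):
        p, n = self.write(tmp_path, [("q1", "zzz")], [("q1", "d5")])
        with pytest.raises(KeyError, match="zzz"):
            read_pair_labels(p, n, task)

    def test_write_read_round_trip(self, tmp_path, task):
        labels = PairLabelSet((("a", "b"),), (("d3", "q1"),))
        write_pair_labels(labels, tmp_path / "p.txt", tmp_path / "n.txt")
        back = read_pair_labels(tmp_path / "p.txt", tmp_path / "n.txt", task)
        assert set(back.positives) == {("a", "b")}


class TestRankingDataset:
    def make_labels(self, n_queries, cands=3):
        pos = tuple((f"q{i}", f"q{i}d0") for i in range(n_queries))
        neg = tuple(
            (f"q{i}", f"q{i}d{j}") for i in range(n_queries) for j in range(1, cands)
        )
        ids = sorted({x for pair in pos + neg for x in pair})
        task = TaskSpec(
            "heterogeneous",
            corpus_of([f"q{i}" for i in range(n_queries)], np.eye(n_queries)),
            corpus_of(
                [i for i in ids if "d" in i], np.eye(len([i for i in ids if "d" in i]))
            ),
        )
        return task, PairLabelSet(pos, neg)

    def test_split_counts_and_determinism(self):
        task, labels = self.make_labels(10)
        ds1 = build_ranking_dataset(task, labels, (0.6, 0.2, 0.2), seed=7)
        ds2 = build_ranking_dataset(task, labels, (0.6, 0.2, 0.2), seed=7)
        sizes = {p: len(ds1.queries_in(p)) for p in ("train", "valid", "test")}
        assert sizes == {"train": 6, "valid": 2, "test": 2}
        assert ds1.partition == ds2.partition

    def test_groups_hold_all_candidates_of_a_query(self):
        task, labels = self.make_labels(4)
        ds = build_ranking_dataset(task, labels, seed=0)
        group = ds.groups["q0"]
        assert sorted(rel for _, rel in group) == [0, 0, 1]

    def test_partition_independent_of_input_order(self):
        task, labels = self.make_labels(8)
        shuffled = PairLabelSet(tuple(reversed(labels.positives)), labels.negatives)
        ds1 = build_ranking_dataset(task, labels, seed=3)
        ds2 = build_ranking_dataset(task, shuffled, seed=3)
        assert ds1.partition == ds2.partition

    def test_too_few_queries_for_split_rejected(self):
        task, labels = self.make_labels(2)
        with pytest.raises(ValueError):
            build_ranking_dataset(task, labels, (0.6, 0.2, 0.2), seed=0)

    def test_no_query_straddles_partitions(self):
        task, labels = self.make_labels(10)
        ds = build_ranking_dataset(task, labels, seed=11)
        for part in ("train", "valid", "test"):
            pairs, _, gids = ds.pairs_in(part)
            for (q, _), g in zip(pairs, gids):
                assert ds.partition[q] == part and g == q
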