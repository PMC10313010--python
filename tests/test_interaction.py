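"""Interaction operators (matrix, histogram, kernels) and matchers."""

import numpy as np
import pytest

from seqsimrank.base import load_scorer
from seqsimrank.interaction import (
    INTERACTION_MODELS,
    HistogramSpec,
    InteractionHyper,
    KernelBank,
    interaction_matrix,
    kernel_features,
    matching_histogram,
    train_interaction_model,
)
from seqsimrank.metrics import auc_score


class TestInteractionMatrix:
    def test_identical_single_tokens(self):
        np.testing.assert_allclose(
            interaction_matrix([[1.0, 0.0]], [[1.0, 0.0]]), [[1.0]]
        )

    def test_orthogonal_single_tokens(self):
        np.testing.assert_allclose(
            interaction_matrix([[1.0, 0.0]], [[0.0, 1.0]]), [[0.0]]
        )

    def test_cosine_hand_value(self):
        np.testing.assert_allclose(
            interaction_matrix([[3.0, 4.0]], [[4.0, 3.0]]), [[0.96]], atol=1e-12
        )

    def test_zero_row_cosine_defined_as_zero(self):
        M = interaction_matrix([[0.0, 0.0]], [[1.0, 1.0]])
        assert M[0, 0] == 0.0

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            interaction_matrix([[1.0, 2.0]], [[1.0, 2.0, 3.0]])

    @pytest.mark.parametrize("measure", ["cosine", "dot"])
    def test_transpose_identity(self, rng, measure):
        A = rng.normal(size=(4, 6))
        B = rng.normal(size=(7, 6))
        np.testing.assert_array_equal(
            interaction_matrix(A, B, measure), interaction_matrix(B, A, measure).T
        )


class TestMatchingHistogram:
    def test_two_bin_hand_case(self):
        h = matching_histogram([1.0, 0.5, -0.5], HistogramSpec(bins=2))
        np.testing.assert_allclose(h, [np.log(2), np.log(3)], atol=1e-12)

    def test_all_mid_values_in_upper_bin(self):
        h = matching_histogram([0.5, 0.5, 0.5], HistogramSpec(bins=2))
        np.testing.assert_allclose(h, [0.0, np.log(4)], atol=1e-12)

    def test_top_edge_closed(self):
        h = matching_histogram([1.0], HistogramSpec(bins=2))
        assert h[-1] == pytest.approx(np.log(2))

    def test_count_conservation(self, rng):
        spec = HistogramSpec(bins=30)
        for _ in range(50):
            row = rng.uniform(-1, 1, size=rng.integers(1, 40))
            h = matching_histogram(row, spec)
            assert np.sum(np.exp(h) - 1) == pytest.approx(len(row), abs=1e-9)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            matching_histogram([], HistogramSpec())

    def test_out_of_range_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            matching_histogram([1.5], HistogramSpec())


class TestKernelFeatures:
    def exact_bank(self, mu, sigma):
        # a custom bank still needs its exact-match kernel; put it first
        return KernelBank(centers=(1.0, mu), widths=(1e-3, sigma))

    def test_exact_match_kernel_gives_zero_log(self):
        bank = KernelBank(centers=(1.0,), widths=(1e-3,))
        np.testing.assert_allclose(kernel_features([[1.0]], bank), [0.0], atol=1e-12)

    def test_hand_computed_soft_kernel_value(self):
        bank = self.exact_bank(0.0, 1.0)
        phi = kernel_features([[1.0, 0.0]], bank)
        expected = np.log(np.exp(-0.5) + 1.0)
        assert phi[1] == pytest.approx(expected, abs=1e-9)

    def test_rows_contribute_additively(self):
        bank = KernelBank(centers=(1.0,), widths=(1e-3,))
        np.testing.assert_allclose(
            kernel_features([[1.0], [1.0]], bank), [0.0], atol=1e-12
        )

    def test_moving_entries_toward_center_does_not_decrease_feature(self, rng):
        bank = self.exact_bank(0.3, 0.2)
        M = rng.uniform(-1, 1, size=(3, 5))
        closer = M + 0.5 * (0.3 - M)  # every entry moved toward mu=0.3
        assert kernel_features(closer, bank)[1] >= kernel_features(M, bank)[1]

    def test_invalid_banks_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KernelBank(centers=(1.0, 0.0), widths=(1e-3, 0.0))
        with pytest.raises(ValueError, match="exact-match"):
            KernelBank(centers=(0.5,), widths=(0.1,))
        with pytest.raises(ValueError, match="within"):
            KernelBank(centers=(1.0, 2.0), widths=(1e-3, 0.1))

    def test_default_bank_layout(self):
        bank = KernelBank()
        assert len(bank) == 11
        assert bank.centers[0] == 1.0 and bank.widths[0] == pytest.approx(1e-3)


class TestInteractionTraining:
    def test_knrm_recovers_planted_signal(self, homo_matrix_dataset):
        scorer = train_interaction_model("knrm", homo_matrix_dataset, seed=1)
        pairs, y, _ = homo_matrix_dataset.pairs_in("test")
        assert auc_score(scorer.score_pairs(pairs, homo_matrix_dataset.task), y) >= 0.85

    @pytest.mark.parametrize("arch", ["drmm", "drmm_tks", "duet", "match_lstm"])
    def test_all_architectures_train_above_chance(self, homo_matrix_dataset, arch):
        hyper = InteractionHyper(epochs=15)
        scorer = train_interaction_model(arch, homo_matrix_dataset, hyper, seed=1)
        pairs, y, _ = homo_matrix_dataset.pairs_in("test")
        s = scorer.score_pairs(pairs, homo_matrix_dataset.task)
        assert np.all((s > 0) & (s < 1))
        assert auc_score(s, y) >= 0.8

    def test_same_seed_identical_scores(self, homo_matrix_dataset):
        a = train_interaction_model("knrm", homo_matrix_dataset, seed=4)
        b = train_interaction_model("knrm", homo_matrix_dataset, seed=4)
        pairs, _, _ = homo_matrix_dataset.pairs_in("test")
        np.testing.assert_array_equal(
            a.score_pairs(pairs, homo_matrix_dataset.task),
            b.score_pairs(pairs, homo_matrix_dataset.task),
        )

    def test_drmm_tks_pads_when_k_exceeds_candidate_length(self, homo_matrix_dataset):
        hyper = InteractionHyper(top_k=50, epochs=2)  # candidates have 8 tokens
        scorer = train_interaction_model("drmm_tks", homo_matrix_dataset, hyper, seed=0)
        pairs, _, _ = homo_matrix_dataset.pairs_in("valid")
        inputs = scorer._inputs(pairs[:3], homo_matrix_dataset.task)
        assert inputs["T"].shape[-1] == 50
        assert np.all(inputs["T"][:, :, 8:] == 0)

    def test_vector_layout_rejected_with_advice(self, homo_dataset):
        with pytest.raises(ValueError, match="matrix-layout"):
            train_interaction_model("knrm", homo_dataset, seed=0)

    def test_unknown_architecture_rejected(self, homo_matrix_dataset):
        with pytest.raises(ValueError, match="drmm"):
            train_interaction_model("bert", homo_matrix_dataset, seed=0)

    def test_homogeneous_scoring_is_order_deterministic(self, homo_matrix_dataset):
        # the lexicographically smaller id takes the query role, so both
        # orientations produce the same (deterministic) score
        scorer = train_interaction_model(
            "knrm", homo_matrix_dataset, InteractionHyper(epochs=5), seed=2
        )
        pairs, _, _ = homo_matrix_dataset.pairs_in("test")
        fwd = scorer.score_pairs(pairs[:50], homo_matrix_dataset.task)
        bwd = scorer.score_pairs(
            [(b, a) for a, b in pairs[:50]], homo_matrix_dataset.task
        )
        np.testing.assert_array_equal(fwd, bwd)

    def test_persistence_round_trip(self, homo_matrix_dataset, tmp_path):
        scorer = train_interaction_model(
            "drmm", homo_matrix_dataset, InteractionHyper(epochs=3), seed=1
        )
        scorer.save(tmp_path / "drmm.scorer")
        loaded = load_scorer(tmp_path / "drmm.scorer")
        pairs, _, _ = homo_matrix_dataset.pairs_in("valid")
        np.testing.assert_array_equal(
            scorer.score_pairs(pairs, homo_matrix_dataset.task),
            loaded.score_pairs(pairs, homo_matrix_dataset.task),
        )
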