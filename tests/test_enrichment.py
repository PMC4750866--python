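"""AIM estimation, likelihood ratios, z-scores, R matrices, networks, clustering."""

import math

import numpy as np
import pytest

from avaseq import enrichment as enr
from avaseq import synthetic, vlmc
from avaseq.enrichment import (
    AIMModel,
    ConditionalLogLikMatrix,
    DegenerateVarianceError,
    build_aim,
    cluster_contexts,
    conditional_loglik_matrix,
    cosine_similarity_matrix,
    digram_class_test,
    enriched_network,
    enumerate_run_order,
    likelihood_ratio,
    permutation_enrichment,
    sequence_probability,
    zscore,
)


class TestBuildAIM:
    def test_hand_transition_counting(self, hand_sequence):
        aim = build_aim(hand_sequence)
        assert aim.P00 == pytest.approx(1 / 3)
        assert aim.P0b == pytest.approx(2 / 3)
        assert aim.Pb0 == pytest.approx(2 / 5)
        assert aim.Pbb == pytest.approx(3 / 5)
        assert np.allclose(aim.burst_rates, [3 / 5, 2 / 5])
        P = aim.transition_matrix
        assert P[0, 1] == pytest.approx(2 / 5)
        assert P[0, 2] == pytest.approx(4 / 15)
        assert P[1, 2] == pytest.approx(6 / 25)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_recovers_generating_parameters(self):
        cfg = synthetic.SleepSynthConfig(n_symbols=100_000, seed=13)
        seq, chain = synthetic.generate_burst_markov(cfg)
        aim = build_aim(seq, alphabet_size=16)
        n0 = (seq[:-1] == 0).sum()
        se = np.sqrt(cfg.p00 * (1 - cfg.p00) / n0)
        assert abs(aim.P00 - cfg.p00) < 3 * se
        nb = (seq[:-1] != 0).sum()
        se_b = np.sqrt(cfg.p_b0 * (1 - cfg.p_b0) / nb)
        assert abs(aim.Pb0 - cfg.p_b0) < 3 * se_b

    def test_no_burst_to_burst_transitions(self):
        aim = build_aim(np.array([0, 1, 0, 2, 0, 1, 0]))
        assert aim.Pbb == 0.0
        P = aim.transition_matrix
        assert np.allclose(P[1:, 0], 1.0)

    def test_unestimable_without_both_symbol_kinds(self):
        with pytest.raises(ValueError):
            build_aim(np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            build_aim(np.ones(10, dtype=int))

    def test_printed_variant_rows_do_not_normalize(self, hand_sequence):
        aim = build_aim(hand_sequence, variant="printed")
        P = aim.transition_matrix
        # the printed burst->burst formula P_AI(i|j) = P_i leaves burst rows
        # summing to Pb0 + 1
        assert P[1].sum() == pytest.approx(aim.Pb0 + 1.0)


class TestSequenceProbability:
    def test_hand_value(self, hand_sequence):
        aim = build_aim(hand_sequence)
        assert sequence_probability(aim, [0, 1]) == pytest.approx((4 / 9) * (2 / 5))

    def test_empty_sequence_probability_one(self, hand_sequence):
        aim = build_aim(hand_sequence)
        assert sequence_probability(aim, []) == 1.0

    def test_deterministic_chain_cycle(self):
        lv = {
            0: (np.array([0]), np.array([[0.0, 0.5, 0.5]])),
            1: (np.array([1, 2]), np.array([[0, 0, 1], [0, 1, 0]], dtype=float)),
        }
        m = vlmc.VLMCModel(3, 1, 0.0, lv)
        assert sequence_probability(m, [1, 2, 1, 2]) == pytest.approx(0.5)


class TestLikelihoodRatio:
    def test_identity_when_fitted_equals_aim(self, hand_sequence):
        aim = build_aim(hand_sequence)
        for seq in [(0, 1), (1, 2), (2, 1, 0)]:
            assert likelihood_ratio(aim, aim, seq).likelihood_ratio == \
                pytest.approx(1.0)

    def test_hand_ratio(self):
        marg = np.array([0.4, 0.3, 0.3])
        aim = AIMModel(P00=0.5, Pb0=0.4, burst_rates=np.array([0.6, 0.4]),
                       marginal=marg)
        lv = {
            0: (np.array([0]), np.array([marg])),
            1: (np.array([1]), np.array([[0.3, 0.2, 0.5]])),
        }
        fitted = vlmc.VLMCModel(3, 1, 0.0, lv)
        res = likelihood_ratio(fitted, aim, [1, 2])
        # P_AI(2|1) = Pbb * P_2 = 0.6 * 0.4 = 0.24; equal marginals cancel
        assert res.likelihood_ratio == pytest.approx(0.5 / 0.24)

    def test_planted_enrichment_recovered(self, planted_first_order):
        cfg, seq, _ = planted_first_order
        fitted = vlmc.fit_pst(seq, 1, alphabet_size=16)
        aim = build_aim(seq, alphabet_size=16, gamma=0.001)
        res = likelihood_ratio(fitted, aim, cfg.run_sequence)
        assert res.likelihood_ratio > 1.0


class TestZScore:
    def test_hand_arithmetic(self):
        z, p, degen = zscore([1, 1, 1, 1, 1, 1, 1, 1, 1, -1])
        assert z == pytest.approx(0.8 / 0.6)
        assert p == pytest.approx(0.0912, abs=2e-4)
        assert not degen

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateVarianceError):
            zscore(np.zeros(10))

    def test_constant_nonzero_infinite_with_flag(self):
        z, p, degen = zscore(np.full(10, 0.5))
        assert math.isinf(z) and z > 0 and p == 0.0 and degen

    def test_symmetric_folds_give_half(self):
        z, p, _ = zscore([-2, -1, 1, 2])
        assert z == 0.0 and p == pytest.approx(0.5)


class TestRunOrderEnumeration:
    @pytest.mark.parametrize("m,count", [(2, 1), (3, 4), (7, 120)])
    def test_counts(self, m, count):
        seqs = enumerate_run_order(tuple(range(1, m + 1)))
        assert len(seqs) == count == 2 ** m - m - 1

    def test_order_preserved_with_gaps(self):
        seqs = enumerate_run_order((1, 3, 4))
        assert set(seqs) == {(1, 3), (1, 4), (3, 4), (1, 3, 4)}

    def test_too_short(self):
        with pytest.raises(ValueError):
            enumerate_run_order((1,))


class TestPermutationEnrichment:
    def test_identity_model_flat_ratios(self, hand_sequence):
        aim = build_aim(hand_sequence)
        ratios, run_L, q = permutation_enrichment(aim, aim, (1, 2))
        assert ratios.size == 2
        assert np.allclose(ratios, 1.0)
        assert run_L == pytest.approx(1.0)

    def test_guard_on_large_m(self):
        with pytest.raises(ValueError):
            permutation_enrichment(None, None, tuple(range(1, 12)))

    def test_planted_run_in_top_quantile(self, planted_first_order):
        cfg, seq, _ = planted_first_order
        fitted = vlmc.fit_pst(seq, 1, alphabet_size=16)
        aim = build_aim(seq, alphabet_size=16, gamma=0.001)
        ratios, _, q = permutation_enrichment(fitted, aim, cfg.run_sequence)
        assert ratios.size == 5040
        assert q <= 0.25


class TestConditionalLogLik:
    def test_identity_is_zero_matrix(self, hand_sequence):
        aim = build_aim(hand_sequence, gamma=0.001)
        # a depth-1 "fitted" model with exactly the AIM conditionals
        A = aim.alphabet_size
        lv = {
            0: (np.array([0]), np.array([aim.cond_row(())])),
            1: (np.arange(A), np.array([aim.cond_row((j,)) for j in range(A)])),
        }
        fitted = vlmc.VLMCModel(A, 1, 0.001, lv)
        R = conditional_loglik_matrix(fitted, aim)
        assert np.allclose(R.values, 0.0, atol=1e-12)

    def test_twofold_upregulation_is_one(self):
        aim = AIMModel(P00=0.5, Pb0=0.4, burst_rates=np.array([0.6, 0.4]),
                       marginal=np.array([0.4, 0.36, 0.24]))
        row = np.array([0.28, 0.24, 0.48])  # P(2|1) = 0.48 vs AIM 0.24
        lv = {0: (np.array([0]), np.array([aim.marginal])),
              1: (np.array([1]), np.array([row]))}
        fitted = vlmc.VLMCModel(3, 1, 0.0, lv)
        R = conditional_loglik_matrix(fitted, aim)
        i = R.contexts.index((1,))
        assert R.values[i, 2] == pytest.approx(1.0)

    def test_entries_finite_with_smoothing(self, planted_first_order):
        _, seq, _ = planted_first_order
        fitted = vlmc.fit_pst(seq, 2, alphabet_size=16)
        aim = build_aim(seq, alphabet_size=16, gamma=0.001)
        R = conditional_loglik_matrix(fitted, aim)
        assert np.all(np.isfinite(R.values))


class TestEnrichedNetwork:
    def test_zero_matrix_empty_network(self):
        R = ConditionalLogLikMatrix([(1,), (2,)], np.zeros((2, 3)))
        G = enriched_network(R)
        assert G.number_of_edges() == 0

    def test_median_threshold_halves_arcs(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (5, 6))
        R = ConditionalLogLikMatrix([(i,) for i in range(1, 6)], vals)
        full = enriched_network(R, 0.0).number_of_edges()
        pos = vals[:, 1:][vals[:, 1:] > 0]
        half = enriched_network(R, float(np.median(pos))).number_of_edges()
        assert abs(half - full / 2) <= 1

    def test_planted_run_arcs_present(self, planted_first_order):
        cfg, seq, _ = planted_first_order
        fitted = vlmc.fit_pst(seq, 1, alphabet_size=16, prune=False)
        aim = build_aim(seq, alphabet_size=16, gamma=0.001)
        R1 = enr.first_order_loglik_matrix(fitted, aim)
        G = enriched_network(R1, 0.0, run_sequence=cfg.run_sequence)
        for a, b in zip(cfg.run_sequence[:-1], cfg.run_sequence[1:]):
            assert G.has_edge(a, b)
            assert G.edges[a, b]["run_order"]


@pytest.fixture(scope="module")
def null_R():
    cfg = synthetic.SleepSynthConfig(n_symbols=30_000, seed=60)
    seq, _ = synthetic.generate_burst_markov(cfg)
    fitted = vlmc.fit_pst(seq, 1, alphabet_size=16, prune=False)
    aim = build_aim(seq, alphabet_size=16, gamma=0.001)
    return enr.first_order_loglik_matrix(fitted, aim)


class TestDigramClassTest:
    def test_null_labels_not_significant(self, null_R):
        classes = {i: "place" if i <= 7 else "other" for i in range(1, 16)}
        res = digram_class_test(null_R, classes, n_perm=200, seed=1)
        assert all(p > 0.05 for p in res.p_values.values())

    def test_shifted_class_detected(self, null_R):
        classes = {i: "place" if i <= 7 else "other" for i in range(1, 16)}
        shifted = ConditionalLogLikMatrix(null_R.contexts, null_R.values.copy())
        for i, ctx in enumerate(shifted.contexts):
            if ctx[0] <= 7:
                shifted.values[i, 1:8] += 1.0
        res = digram_class_test(shifted, classes, n_perm=200, seed=1)
        assert res.p_values[("place-place", "place-other")] < 0.05
        assert res.p_values[("place-place", "other-other")] < 0.05

    def test_zero_permutations_rejected(self, null_R):
        with pytest.raises(ValueError):
            digram_class_test(null_R, {1: "place"}, n_perm=0)

    def test_empty_class_skipped(self, null_R):
        classes = {i: "place" for i in range(1, 16)}
        res = digram_class_test(null_R, classes, n_perm=10, seed=0)
        assert res.skipped


class TestClusterContexts:
    def test_identical_rows_similarity_one(self):
        R = ConditionalLogLikMatrix([(1,), (2,)], np.array([[1.0, 2], [1, 2]]))
        cl = cluster_contexts(R)
        assert cl.similarity[0, 1] == pytest.approx(1.0)

    def test_hand_cosine(self):
        sim = cosine_similarity_matrix(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert sim[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_zero_row_similarity_zero(self):
        sim = cosine_similarity_matrix(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert sim[0, 1] == 0.0 and sim[0, 0] == 0.0

    def test_planted_blocks_recovered(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            rows = np.vstack([
                np.tile([1.0, 1, 0, 0, 0], (6, 1)),
                np.tile([0.0, 0, 0, 1, 1], (6, 1)),
            ]) + rng.normal(0, 0.3, (12, 5))
            R = ConditionalLogLikMatrix([(i,) for i in range(12)], rows)
            cl = cluster_contexts(R)
            within = np.mean([cl.similarity[i, j]
                              for i in range(6) for j in range(6) if i != j])
            between = np.mean([cl.similarity[i, j]
                               for i in range(6) for j in range(6, 12)])
            hits += within > between
        assert hits >= 19


def test_aim_generated_digram_ratios_center_on_zero():
    """Fitting the pipeline to AIM data yields log ratios centered on 0."""
    cfg = synthetic.SleepSynthConfig(n_symbols=50_000, seed=77)
    seq, _ = synthetic.generate_burst_markov(cfg)
    fitted = vlmc.fit_pst(seq, 1, alphabet_size=16, prune=False)
    aim = build_aim(seq, alphabet_size=16, gamma=0.001)
    R1 = enr.first_order_loglik_matrix(fitted, aim)
    vals = R1.values[:, 1:].ravel()
    assert abs(np.median(vals)) < 0.05
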