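"""PST fitting, log-loss, cross validation, scrambling, word-rate prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avaseq import vlmc
from avaseq.vlmc import (
    VLMCModel,
    cross_validate,
    fit_pst,
    log_loss,
    predicted_word_frequencies,
    scramble_bursts,
    word_rate,
)


def brute_force_conditionals(seq, k, alphabet_size):
    """Independent d-gram oracle: empirical P(s | last k symbols)."""
    out = {}
    for i in range(k, len(seq)):
        ctx = tuple(int(x) for x in seq[i - k:i])
        row = out.setdefault(ctx, np.zeros(alphabet_size))
        row[seq[i]] += 1
    return {c: r / r.sum() for c, r in out.items()}


class TestFitPST:
    def test_depth0_is_smoothed_marginal(self):
        seq = np.array([0, 1, 1, 2, 2, 2])
        m = fit_pst(seq, 0, gamma=0.01, alphabet_size=3)
        phat = np.array([1, 2, 3]) / 6
        assert np.allclose(m.levels[0][1][0], (1 - 3 * 0.01) * phat + 0.01)

    def test_alternating_sequence_learns_transitions(self):
        seq = np.array([1, 2] * 500)
        m = fit_pst(seq, 1, alphabet_size=3)
        assert m.cond_row((1,))[2] >= 1 - 3 * m.gamma
        assert m.cond_row((2,))[1] >= 1 - 3 * m.gamma

    def test_iid_sequence_prunes_to_depth0(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            seq = rng.integers(0, 2, 5000)
            m = fit_pst(seq, 2, alphabet_size=2, gamma=0.001)
            deep = sum(len(c) > 0 for c in m.contexts())
            hits += deep == 0
        assert hits >= 8  # ratio test r=1.05 defeats sampling noise

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_unpruned_matches_brute_force_dgram_oracle(self, depth):
        rng = np.random.default_rng(depth)
        seq = rng.integers(0, 4, 500)
        m = fit_pst(seq, depth, gamma=1e-9, alphabet_size=4, prune=False)
        oracle = brute_force_conditionals(seq, depth, 4)
        for ctx, row in oracle.items():
            assert np.allclose(m.cond_row(ctx), row, atol=1e-6)

    def test_tree_property_suffix_closure(self, planted_first_order):
        _, seq, _ = planted_first_order
        m = fit_pst(seq[:20_000], 3, alphabet_size=16)
        stored = set(m.contexts())
        for ctx in stored:
            while len(ctx) > 0:
                ctx = ctx[1:]
                assert ctx in stored or ctx == ()

    def test_rows_are_distributions_above_floor(self, planted_first_order):
        _, seq, _ = planted_first_order
        m = fit_pst(seq[:20_000], 2, alphabet_size=16)
        for _, rows in m.levels.values():
            if rows.size:
                assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)
                assert rows.min() >= m.gamma - 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_pst(np.array([]), 1)
        with pytest.raises(ValueError):
            fit_pst(np.array([0, 5]), 1, alphabet_size=3)
        with pytest.raises(ValueError):
            fit_pst(np.array([0, 1]), 1, r=0.9)


class TestLogLoss:
    def test_uniform_model_closed_form(self):
        lv = {0: (np.array([0]), np.array([[0.25] * 4]))}
        m = VLMCModel(4, 0, 0.0, lv)
        assert log_loss(m, np.array([0, 1, 2, 3, 2])) == pytest.approx(2.0)

    def test_deterministic_model_zero_bits(self):
        lv = {0: (np.array([0]), np.array([[1.0, 0.0]]))}
        m = VLMCModel(2, 0, 0.0, lv)
        assert log_loss(m, np.zeros(10, dtype=int)) == pytest.approx(0.0)

    def test_first_order_hand_arithmetic(self):
        lv = {
            0: (np.array([0]), np.array([[0.0, 0.5, 0.5]])),
            1: (np.array([1, 2]), np.array([[0.0, 0.1, 0.9], [0.0, 0.8, 0.2]])),
        }
        m = VLMCModel(3, 1, 0.0, lv)
        expected = -(np.log2(0.5) + 3 * np.log2(0.9) + 2 * np.log2(0.8)) / 6
        assert log_loss(m, np.array([1, 2, 1, 2, 1, 2])) == pytest.approx(expected)

    def test_training_loss_nonincreasing_in_depth_unpruned(self):
        rng = np.random.default_rng(3)
        seq = rng.integers(0, 3, 2000)
        losses = [
            log_loss(fit_pst(seq, d, gamma=1e-6, alphabet_size=3, prune=False), seq)
            for d in range(4)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))


class TestCrossValidate:
    def test_ni_normalization_definitional(self, planted_first_order):
        _, seq, _ = planted_first_order
        cv = cross_validate(seq[:20_000], depths=[0, 1, 2], alphabet_size=16)
        assert cv.normalized_information[0] == 0.0
        sel_idx = cv.depths.index(cv.selected_depth)
        assert cv.normalized_information[sel_idx] == pytest.approx(1.0)

    def test_fold_boundaries_do_not_split_words(self, planted_first_order):
        _, seq, _ = planted_first_order
        cv = cross_validate(seq, depths=[0, 1], alphabet_size=16)
        assert len(cv.fold_spans) == 10
        for a, _ in cv.fold_spans[1:]:
            assert seq[a] == 0 or seq[a - 1] == 0

    def test_too_few_symbols(self):
        with pytest.raises(ValueError):
            cross_validate(np.array([0, 1, 0]), folds=10)

    def test_deterministic(self, planted_first_order):
        _, seq, _ = planted_first_order
        a = cross_validate(seq[:10_000], depths=[0, 1], alphabet_size=16)
        b = cross_validate(seq[:10_000], depths=[0, 1], alphabet_size=16)
        assert np.array_equal(a.losses, b.losses)


class TestScramble:
    def test_identical_bursts_invariant(self):
        assert scramble_bursts(np.array([0, 1, 1, 0]), 5).tolist() == [0, 1, 1, 0]

    def test_two_orders_equally_likely(self):
        hits = sum(scramble_bursts(np.array([1, 2, 0]), s).tolist() == [1, 2, 0]
                   for s in range(1000))
        assert abs(hits - 500) < 3 * np.sqrt(250)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=0, max_size=50), st.integers(0, 100))
    def test_conservation(self, symbols, seed):
        seq = np.array(symbols, dtype=int)
        out = scramble_bursts(seq, seed)
        assert np.array_equal(out == 0, seq == 0)
        assert np.array_equal(np.sort(out), np.sort(seq))


class TestWordRates:
    def test_deterministic_cycle(self):
        lv = {
            0: (np.array([0]), np.array([[0.0, 1 / 3, 1 / 3, 1 / 3]])),
            1: (np.array([1, 2, 3]),
                np.array([[0, 0, 1, 0], [0, 0, 0, 1], [0, 1, 0, 0]], dtype=float)),
        }
        m = VLMCModel(4, 1, 0.0, lv)
        assert word_rate(m, np.array([1, 2, 3])) == pytest.approx(1 / 3)
        assert predicted_word_frequencies(m, [np.array([1, 2, 3])], 300)[0] == \
            pytest.approx(100.0)

    def test_aim_word_rate_matches_simulation_count(self):
        from avaseq import synthetic
        from avaseq.enrichment import AIMModel
        cfg = synthetic.SleepSynthConfig(
            n_cells=5, run_sequence=(1, 2), n_symbols=300_000, seed=9)
        seq, chain = synthetic.generate_burst_markov(cfg)
        aim = AIMModel(P00=cfg.p00, Pb0=cfg.p_b0, burst_rates=cfg.burst_rates,
                       marginal=chain.stationary())
        for word in [(1, 2), (0, 1, 2), (3, 3)]:
            w = np.array(word)
            rate = word_rate(aim, w)
            n_pos = seq.size - w.size + 1
            hits = np.ones(n_pos, dtype=bool)
            for j, s in enumerate(w):
                hits &= seq[j:n_pos + j] == s
            expected = rate * n_pos
            assert abs(hits.sum() - expected) < 4 * np.sqrt(expected)

    def test_unknown_symbol_rejected(self):
        lv = {0: (np.array([0]), np.array([[0.5, 0.5]]))}
        m = VLMCModel(2, 0, 0.0, lv)
        with pytest.raises(ValueError):
            word_rate(m, np.array([3]))


def test_serialization_roundtrip(planted_first_order):
    _, seq, _ = planted_first_order
    m = fit_pst(seq[:10_000], 2, alphabet_size=16)
    m2 = VLMCModel.from_dict(m.to_dict())
    assert m2.alphabet_size == m.alphabet_size
    for k in m.levels:
        assert np.array_equal(m.levels[k][0], m2.levels[k][0])
        assert np.allclose(m.levels[k][1], m2.levels[k][1])
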