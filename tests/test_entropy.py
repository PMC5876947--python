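"""Entropy model: closed forms, bounds, and brute-force equivalence."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrstruct.entropy import (CharModel, EntropyInput, TaggedSegment,
                               entropy_raw, entropy_report,
                               entropy_structured, entropy_tagged,
                               entropy_temporal, node_entropy,
                               segment_distribution, segment_entropy,
                               term_probability)
from emrstruct.lexicon import POSWeightTable, Token
from emrstruct.pipeline import process_note
from emrstruct.structuring import structure_text


class TestRaw:
    def test_per_character_value_for_default_alphabet(self):
        r = entropy_raw("痛", CharModel(2500))
        assert r.per_char == pytest.approx(math.log2(2500), abs=1e-9)
        assert r.per_char == pytest.approx(11.2877, abs=1e-4)

    def test_empty_text_is_zero(self):
        r = entropy_raw("", CharModel(2500))
        assert r.total == 0.0 and r.per_char == 0.0

    def test_total_scales_with_length(self):
        assert entropy_raw("0123456789", CharModel(2)).total \
            == pytest.approx(10.0)


class TestStructured:
    def test_certain_single_word_segment_is_zero(self):
        inp = EntropyInput(sentences=[[(1, 1.0)]])
        assert entropy_structured(inp) == pytest.approx(0.0)

    def test_two_segment_hand_value(self):
        # two segments of 2 words each, uniform word probability 1/4:
        # each contributes log2(4)/2 = 1 bit, one sentence -> 2 bits
        inp = EntropyInput(sentences=[[(2, 0.25), (2, 0.25)]])
        assert entropy_structured(inp) == pytest.approx(2.0)

    def test_doubling_word_count_strictly_decreases(self):
        h1 = entropy_structured(EntropyInput(sentences=[[(2, 0.25)]]))
        h2 = entropy_structured(EntropyInput(sentences=[[(4, 0.25)]]))
        assert h2 == pytest.approx(h1 / 2) and h2 < h1

    def test_mean_over_sentences(self):
        one = EntropyInput(sentences=[[(2, 0.25)]])
        two = EntropyInput(sentences=[[(2, 0.25)], [(2, 0.25)]])
        assert entropy_structured(one) == \
            pytest.approx(entropy_structured(two))

    def test_empty_input_is_zero(self):
        assert entropy_structured(EntropyInput(sentences=[])) == 0.0

    def test_explicit_distribution_accepted(self):
        inp = EntropyInput(sentences=[[(2, [0.5, 0.5])]])
        assert entropy_structured(inp) == pytest.approx(0.5)


class TestTermProbability:
    def test_noun_beats_function_at_equal_length(self):
        m, w = CharModel(2500), POSWeightTable()
        assert term_probability(Token("咽痛", "noun"), m, w) \
            > term_probability(Token("石史", "function"), m, w)

    def test_longer_term_has_smaller_base_probability(self):
        m, w = CharModel(2500), POSWeightTable()
        assert term_probability(Token("疟疾病", "noun"), m, w) \
            < term_probability(Token("咽痛", "noun"), m, w)

    def test_single_token_renormalizes_to_one(self):
        assert segment_distribution([Token("咽痛", "noun")]) \
            == pytest.approx([1.0])


class TestTagged:
    def test_single_token_segment_has_zero_entropy(self):
        assert segment_entropy([Token("咽痛", "noun")]) \
            == pytest.approx(0.0)

    def test_two_equal_probability_tokens_give_one_bit(self):
        toks = [Token("咽痛", "noun"), Token("发热", "noun")]
        assert segment_entropy(toks) == pytest.approx(1.0)

    @pytest.mark.parametrize("surfaces", [
        ["咽痛", "发热"], ["否认", "肝炎", "结核"],
        ["给予", "阿奇霉素", "抗感染", "无效"],
    ])
    def test_entropy_bounded_by_log_token_count(self, surfaces):
        toks = [Token(s, "noun") for s in surfaces]
        assert segment_entropy(toks) <= math.log2(len(toks)) + 1e-12

    def test_aggregation_divides_by_term_count_and_averages(self):
        toks = [Token("咽痛", "noun"), Token("发热", "noun")]
        seg = TaggedSegment(tokens=toks, sentence_index=0)
        assert entropy_tagged([seg]) == pytest.approx(0.5)
        two = [TaggedSegment(tokens=toks, sentence_index=i)
               for i in range(2)]
        assert entropy_tagged(two) == pytest.approx(0.5)

    def test_brute_force_oracle_equivalence_small_segments(self):
        """Direct evaluation of the weighted-length probability model and
        its entropy, written independently of the implementation."""
        m, w = CharModel(2500), POSWeightTable()
        cases = [
            [("咽痛", "noun")],
            [("否认", "negation"), ("肝炎", "noun")],
            [("2008年3月11日", "time"), ("出现", "verb"), ("咽痛", "noun")],
            [("高血压", "noun"), ("史", "function"), ("、", "symbol"),
             ("冠心病", "noun"), ("20年", "numeral_unit")],
        ]
        for case in cases:
            toks = [Token(s, p) for s, p in case]
            base = [w[p] * (1 / 2500) ** len(s) for s, p in case]
            z = sum(base)
            probs = [b / z for b in base]
            expected = -sum(p * math.log2(p) for p in probs if p > 0)
            assert segment_entropy(toks, m, w) \
                == pytest.approx(expected, abs=1e-9)


class TestTemporal:
    def test_single_node_returns_its_entropy(self):
        assert entropy_temporal([2.5], [4]) == pytest.approx(2.5)

    def test_equal_shares_average_two_nodes(self):
        assert entropy_temporal([1.0, 3.0], [2, 2]) == pytest.approx(2.0)

    def test_share_weighting_follows_triple_counts(self):
        assert entropy_temporal([1.0, 3.0], [3, 1]) == pytest.approx(1.5)

    def test_uniform_mode_ignores_counts(self):
        assert entropy_temporal([1.0, 3.0], [3, 1], p_t_mode="uniform") \
            == pytest.approx(2.0)

    def test_empty_timeline_is_zero(self):
        assert entropy_temporal([], []) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 5), st.integers(1, 9)),
                    min_size=1, max_size=8))
    def test_convex_combination_bounded_by_extremes(self, nodes):
        hs = [h for h, _ in nodes]
        counts = [c for _, c in nodes]
        h = entropy_temporal(hs, counts)
        assert min(hs) - 1e-9 <= h <= max(hs) + 1e-9

    def test_grounding_discount_shrinks_with_resolved_nodes(self):
        vals = [0.4, 0.2]
        h1 = node_entropy(vals, resolved=True, n_resolved=1)
        h5 = node_entropy(vals, resolved=True, n_resolved=5)
        assert h5 < h1 < node_entropy(vals, resolved=False, n_resolved=5)

    def test_hand_computed_convex_combination(self):
        # three nodes carrying 1, 2 and 1 triples
        h = entropy_temporal([0.4, 0.1, 0.2], [1, 2, 1])
        assert h == pytest.approx(0.25 * 0.4 + 0.5 * 0.1 + 0.25 * 0.2,
                                  abs=1e-12)


class TestReport:
    def test_empty_note_reports_all_zeros(self):
        r = entropy_report("", structure_text(""), {}, None)
        assert (r.h_raw_total, r.h_phase1, r.h_phase2, r.h_phase3) \
            == (0.0, 0.0, 0.0, 0.0)
        assert r.monotone

    def test_phase_ordering_on_worked_example(self, blood_routine_note):
        r = process_note(blood_routine_note).entropy
        assert r.h_phase3 <= r.h_phase2 <= r.h_phase1 <= r.h_raw_per_char
        assert r.monotone and not r.violations

    def test_node_weights_sum_to_one(self, blood_routine_note):
        r = process_note(blood_routine_note).entropy
        assert sum(r.node_weights) == pytest.approx(1.0)

    def test_all_reported_entropies_nonnegative(self, blood_routine_note):
        r = process_note(blood_routine_note).entropy
        for v in (r.h_raw_total, r.h_raw_per_char, r.h_phase1, r.h_phase2,
                  r.h_phase3, *r.node_entropies):
            assert v >= 0.0
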