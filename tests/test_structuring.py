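"""Sentence/segment hierarchy, XML round-trip, and losslessness."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrstruct.correction import PARAGRAPH_SEP
from emrstruct.structuring import (SEGMENT_DELIMITERS, SENTENCE_DELIMITERS,
                                   Segment, canonicalize_delimiters,
                                   from_xml, reconstruct_text,
                                   structure_text, to_xml)


class TestStructure:
    def test_empty_text_yields_empty_hierarchy(self):
        assert structure_text("").sentences == []

    def test_history_sentence_three_segments(self, history_sentence):
        mt = structure_text(history_sentence)
        assert len(mt.sentences) == 1
        assert [s.text for s in mt.sentences[0].segments] == [
            "否认肝炎、结核、疟疾病史",
            "高血压史、冠心病史20年",
            "糖尿病史20年",
        ]

    def test_sentence_and_segment_counts(self):
        mt = structure_text("A，B。C。")
        assert [len(s.segments) for s in mt.sentences] == [2, 1]

    def test_decimal_point_is_not_a_sentence_boundary(self,
                                                      blood_routine_note):
        mt = structure_text(blood_routine_note)
        assert len(mt.sentences) == 1
        texts = [s.text for s in mt.sentences[0].segments]
        assert "WBC2.13 × 10^9/L" in texts

    def test_colon_splits_exam_introducer(self, blood_routine_note):
        mt = structure_text(blood_routine_note)
        texts = [s.text for s in mt.sentences[0].segments]
        assert texts[2] == "在我院进行血常规检查"
        assert mt.sentences[0].segments[2].trailing_delimiter == "："

    def test_trailing_delimiter_produces_no_empty_node(self):
        mt = structure_text("咽痛。")
        assert mt.n_segments == 1

    def test_paragraph_separator_starts_new_paragraph(self):
        mt = structure_text(f"咽痛{PARAGRAPH_SEP}发热")
        assert [s.paragraph_index for s in mt.sentences] == [0, 1]

    def test_segment_count_matches_naive_split_filter_oracle(self):
        text = "A，，B。。C，D；E"
        naive = [
            piece
            for sent in re.split(f"[{re.escape(SENTENCE_DELIMITERS)}]", text)
            for piece in re.split(f"[{re.escape(SEGMENT_DELIMITERS)}]", sent)
            if piece.strip()
        ]
        assert structure_text(text).n_segments == len(naive)

    def test_no_segment_contains_a_delimiter(self, blood_routine_note):
        for seg in structure_text(blood_routine_note).iter_segments():
            assert not any(ch in SEGMENT_DELIMITERS for ch in seg.text)
            assert not any(ch in "。．！？；;" for ch in seg.text)

    def test_blank_segment_rejected_by_invariant(self):
        with pytest.raises(ValueError):
            Segment(text="  ", sentence_index=0, segment_index=0)


class TestXML:
    def test_empty_medical_text_serializes_to_bare_root(self):
        xml = to_xml(structure_text(""))
        assert xml.startswith('<?xml version="1.0" encoding="UTF-8"?>')
        assert "<MedicalText />" in xml or "<MedicalText/>" in xml

    def test_single_segment_document(self):
        xml = to_xml(structure_text("咽痛"))
        assert xml.count("<Sentence") == 1
        assert xml.count("<Segment") == 1
        assert "咽痛" in xml

    @pytest.mark.parametrize("text", [
        "咽痛",
        "A，B。C。",
        "否认肝炎、结核、疟疾病史，高血压史、冠心病史20年，糖尿病史20年",
        "2008年3月11日出现咽痛，在我院进行血常规检查：WBC2.13 × 10^9/L",
    ])
    def test_round_trip_through_parser(self, text):
        mt = structure_text(text)
        assert from_xml(to_xml(mt)) == mt


class TestReconstruct:
    def test_empty(self):
        assert reconstruct_text(structure_text("")) == ""

    def test_three_segment_sentence_rejoins_exactly(self, history_sentence):
        assert reconstruct_text(structure_text(history_sentence)) \
            == history_sentence

    def test_identity_on_delimiter_canonical_text(self):
        text = "出现咽痛，给予治疗。复查血常规"
        assert reconstruct_text(structure_text(text)) == text

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(
        st.lists(st.sampled_from(["咽痛", "发热", "给予治疗", "复查血常规"]),
                 min_size=1, max_size=3),
        min_size=1, max_size=3))
    def test_structure_reconstruct_round_trip_on_canonical_notes(self, sents):
        text = "。".join("，".join(segs) for segs in sents)
        assert canonicalize_delimiters(
            reconstruct_text(structure_text(text))) \
            == canonicalize_delimiters(text)
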