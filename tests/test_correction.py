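"""Correction-rule loading and sequential text normalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrstruct.correction import (PARAGRAPH_SEP, CorrectionRule, RuleSet,
                                  RuleError, correct_text, default_rules,
                                  load_rules)


def _write_rules(tmp_path, content: str):
    p = tmp_path / "rules.tsv"
    p.write_text(content, encoding="utf-8")
    return p


class TestLoadRules:
    def test_two_row_file_preserves_order(self, tmp_path):
        p = _write_rules(tmp_path, "圧\t压\n抦\t病\n")
        rs = load_rules(p)
        assert [(r.original, r.replacement) for r in rs] == \
            [("圧", "压"), ("抦", "病")]

    def test_empty_file_gives_empty_ruleset(self, tmp_path):
        assert len(load_rules(_write_rules(tmp_path, ""))) == 0

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = _write_rules(tmp_path, "# c\n\n圧\t压\n")
        assert len(load_rules(p)) == 1

    def test_duplicate_original_reports_row(self, tmp_path):
        p = _write_rules(tmp_path, "圧\t压\n圧\t庄\n")
        with pytest.raises(RuleError, match="2"):
            load_rules(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_rules(tmp_path / "absent.tsv")

    def test_missing_replacement_column_deletes(self, tmp_path):
        rs = load_rules(_write_rules(tmp_path, "圧\n"))
        assert rs.rules[0].replacement == ""

    def test_packaged_default_rules_load(self):
        assert len(default_rules()) > 0


class TestRuleValidation:
    def test_empty_original_rejected(self):
        with pytest.raises(RuleError):
            CorrectionRule("", "x")

    def test_identity_rule_rejected(self):
        with pytest.raises(RuleError):
            CorrectionRule("x", "x")

    def test_duplicate_in_ruleset_rejected(self):
        with pytest.raises(RuleError):
            RuleSet(rules=[CorrectionRule("a", "b"),
                           CorrectionRule("a", "c")])


class TestCorrectText:
    def test_identity_without_rules(self):
        assert correct_text("abc", RuleSet()) == "abc"

    def test_line_wrap_removed_interior_space_kept(self):
        assert correct_text("a\nb c", RuleSet()) == "ab c"

    def test_blank_line_run_becomes_paragraph_separator(self):
        out = correct_text("主诉段落\n\n现病史段落", RuleSet())
        assert out == f"主诉段落{PARAGRAPH_SEP}现病史段落"
        assert "\n" not in out and "\r" not in out

    def test_sequential_rule_application(self):
        rs = RuleSet(rules=[CorrectionRule("圧", "压")])
        assert correct_text("高血圧20年", rs) == "高血压20年"

    def test_later_rules_see_earlier_output(self):
        rs = RuleSet(rules=[CorrectionRule("a", "b"),
                            CorrectionRule("bb", "c")])
        assert correct_text("ab", rs) == "c"

    def test_zero_width_characters_removed(self):
        assert correct_text("咽​痛﻿", RuleSet()) == "咽痛"

    @pytest.mark.parametrize("text", ["", "咽痛", "a\r\nb", "x\n\n\ny"])
    def test_output_never_contains_newlines(self, text):
        out = correct_text(text, default_rules())
        assert "\n" not in out and "\r" not in out

    def test_length_change_matches_naive_single_pass_oracle(self):
        rules = [CorrectionRule("圧", "压力"), CorrectionRule("抦", "")]
        rs = RuleSet(rules=list(rules))
        text = "高血圧抦圧圧"
        out = correct_text(text, rs)
        expected_delta = 0
        work = text
        for r in rules:
            occurrences = work.count(r.original)
            expected_delta += (len(r.replacement) - len(r.original)) \
                * occurrences
            work = work.replace(r.original, r.replacement)
        assert len(out) - len(text) == expected_delta

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="高血压咽痛 圧abc", max_size=40))
    def test_idempotent_when_replacements_disjoint_from_originals(self, text):
        rs = RuleSet(rules=[CorrectionRule("圧", "压"),
                            CorrectionRule("a", "x")])
        once = correct_text(text, rs)
        assert correct_text(once, rs) == once
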