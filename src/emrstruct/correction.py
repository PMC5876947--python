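"""Text correction: the pre-processing pass over raw EMR free text.

Clinical notes exported from hospital information systems carry artefacts
that break downstream rule matching: hard line wraps inside sentences,
byte-order marks and zero-width characters, full-width digits, and
recurring typos. Correction is an ordered table of literal
``original -> replacement`` substitutions applied after the artefact
sweep; order matters, and later rules see the output of earlier ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "CorrectionRule",
    "RuleSet",
    "load_rules",
    "default_rules",
    "correct_text",
    "PARAGRAPH_SEP",
]

#: Canonical paragraph separator emitted for blank-line runs. It is not a
#: newline/carriage-return, so corrected text stays single-line per the
#: correction contract while the paragraph structure survives for the
#: structuring stage.
PARAGRAPH_SEP = " "

# Zero-width and BOM-like characters removed unconditionally.
_ZERO_WIDTH = re.compile("[\\u200b\\u200c\\u200d\\u2060\\ufeff]")

# A run of blank(-ish) lines is a paragraph break; a single line wrap is an
# artefact and is deleted outright (CJK text has no inter-word spaces, so
# joining without a space is lossless).
_PARA_BREAK = re.compile(r"(?:\r\n|\r|\n)(?:[ \t]*(?:\r\n|\r|\n))+")
_LINE_WRAP = re.compile(r"\r\n|\r|\n")


class RuleError(ValueError):
    """Raised for an invalid correction-rule table."""


@dataclass(frozen=True)
class CorrectionRule:
    """One literal substitution: ``original`` -> ``replacement``.

    ``replacement`` may be empty, which deletes every occurrence.
    """

    original: str
    replacement: str

    def __post_init__(self) -> None:
        if not self.original:
            raise RuleError("correction rule 'original' must be nonempty")
        if self.original == self.replacement:
            raise RuleError(
                f"rule maps {self.original!r} to itself; original must differ "
                "from replacement"
            )


@dataclass
class RuleSet:
    """An ordered correction-rule table; application order is list order."""

    rules: list[CorrectionRule] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for row, rule in enumerate(self.rules, start=1):
            if rule.original in seen:
                raise RuleError(
                    f"duplicate original {rule.original!r} at rule {row} "
                    f"(first seen at rule {seen[rule.original]})"
                )
            seen[rule.original] = row

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterable[CorrectionRule]:
        return iter(self.rules)


def load_rules(path: str | Path) -> RuleSet:
    """Read a correction-rule table from a UTF-8 TSV file.

    Two columns, ``original<TAB>replacement`` (replacement may be empty and
    the column may be missing entirely for deletion rules). ``#`` comment
    lines and blank lines are ignored. Row order is application order.
    Duplicate originals raise :class:`RuleError` with the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"correction-rule file not found: {path}")
    rules: list[CorrectionRule] = []
    seen: dict[str, int] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            original = cols[0]
            replacement = cols[1] if len(cols) > 1 else ""
            if original in seen:
                raise RuleError(
                    f"{path}:{lineno}: duplicate original {original!r} "
                    f"(first at line {seen[original]})"
                )
            seen[original] = lineno
            rules.append(CorrectionRule(original, replacement))
    return RuleSet(rules=rules, source_path=str(path))


def default_rules() -> RuleSet:
    """The packaged default rule table (full-width digit/letter fold plus a
    few common EMR typos). Illustrative, not canonical — hospitals ship
    their own tables."""
    ref = resources.files("emrstruct.data").joinpath("correction_rules.tsv")
    with resources.as_file(ref) as p:
        return load_rules(p)


def _strip_artifacts(text: str) -> str:
    text = _ZERO_WIDTH.sub("", text)
    text = _PARA_BREAK.sub(PARAGRAPH_SEP, text)
    text = _LINE_WRAP.sub("", text)
    return text


def correct_text(text: str, rules: RuleSet | None = None) -> str:
    """Normalize raw note text and apply the rule table sequentially.

    Blank-line runs become the canonical paragraph separator, single line
    wraps are removed (interior spaces are kept), zero-width characters are
    dropped, then each rule is applied in order as a global literal
    replacement (leftmost, non-overlapping). The output contains no
    newline or carriage-return characters.
    """
    out = _strip_artifacts(text)
    if rules is not None:
        for rule in rules:
            out = out.replace(rule.original, rule.replacement)
    return out
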