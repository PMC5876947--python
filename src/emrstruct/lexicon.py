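"""Phrase splitting and coarse part-of-speech tagging.

Clinical Chinese narrative is terse: no inflection, few particles, and a
closed domain vocabulary, so a greedy longest-match tokenizer over a
clinical lexicon recovers the content phrases (否认|肝炎|结核|…|20年)
deterministically. Temporal expressions and number+unit readings are
recognized by pattern before lexicon matching so that 2008年3月11日 or
2.13 × 10^9/L stay atomic. Anything outside the lexicon degrades to
single-character function tokens — never an exception — which keeps the
token stream lossless: concatenating all surfaces reproduces the segment.

POS tags: noun, verb, adjective, numeral_unit, time, negation, function,
symbol. The POS weight table encodes relative importance for the entropy
model (nouns carry more information than function morphemes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .temporal import _TIME_RE

__all__ = [
    "POS_TAGS",
    "Token",
    "POSWeightTable",
    "Lexicon",
    "load_lexicon",
    "default_lexicon",
    "default_weights",
    "tokenize",
    "tag_pos",
    "content_tokens",
]

POS_TAGS = (
    "noun", "verb", "adjective", "numeral_unit", "time", "negation",
    "function", "symbol",
)

DEFAULT_POS_WEIGHTS = {
    "noun": 0.30,
    "verb": 0.20,
    "time": 0.20,
    "numeral_unit": 0.15,
    "adjective": 0.08,
    "negation": 0.04,
    "function": 0.02,
    "symbol": 0.01,
}

# A numeric reading with optional power-of-ten multiplier and unit, kept
# atomic for lab values: 2.13 × 10^9/L, 102g/L, 38.5℃, 80次/分, 95%.
_NUM_UNIT_RE = re.compile(
    r"\d+(?:\.\d+)?(?:\s*[×x]\s*10\^?\d+)?[A-Za-z/%^℃︒°·次分个]*"
)
# ASCII measurement identifiers (WBC, Hb, PLT, CRP ...)
_ASCII_KEY_RE = re.compile(r"[A-Za-z][A-Za-z%]*")

_PUNCT = set("、 ·〈〉《》“”\"'()（）[]【】*+-~^/\\|")


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be nonempty")
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown pos tag {self.pos!r}")

    @property
    def n_w(self) -> int:
        """Term length in characters."""
        return len(self.surface)


@dataclass
class POSWeightTable:
    """pos -> positive importance weight; noun must outweigh function."""

    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POS_WEIGHTS))

    def __post_init__(self) -> None:
        for pos in POS_TAGS:
            if pos not in self.weights:
                raise ValueError(f"missing weight for pos {pos!r}")
            if self.weights[pos] <= 0:
                raise ValueError(f"weight for {pos!r} must be positive")
        if self.weights["noun"] <= self.weights["function"]:
            raise ValueError("noun weight must exceed function weight")

    def __getitem__(self, pos: str) -> float:
        return self.weights[pos]


def default_weights() -> POSWeightTable:
    return POSWeightTable()


class Lexicon:
    """surface -> pos map with longest-match lookup support."""

    def __init__(self, entries: dict[str, str]):
        self.entries = dict(entries)
        self.max_len = max((len(s) for s in entries), default=1)

    def __contains__(self, surface: str) -> bool:
        return surface in self.entries

    def __getitem__(self, surface: str) -> str:
        return self.entries[surface]

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a UTF-8 TSV lexicon ``surface<TAB>pos``; # comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    entries: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected surface<TAB>pos")
            surface, pos = cols[0], cols[1]
            if pos not in POS_TAGS:
                raise ValueError(f"{path}:{lineno}: unknown pos {pos!r}")
            entries[surface] = pos
    return Lexicon(entries)


_default_lexicon: Lexicon | None = None


def default_lexicon() -> Lexicon:
    """The packaged ~160-entry clinical lexicon (cached)."""
    global _default_lexicon
    if _default_lexicon is None:
        ref = resources.files("emrstruct.data").joinpath("lexicon.tsv")
        with resources.as_file(ref) as p:
            _default_lexicon = load_lexicon(p)
    return _default_lexicon


def _pattern_spans(text: str) -> list[tuple[int, int, str]]:
    """Non-overlapping (start, end, pos) spans for temporal and numeric
    patterns; temporal matches take precedence."""
    spans: list[tuple[int, int, str]] = []
    for m in _TIME_RE.finditer(text):
        kind = "numeral_unit" if m.group("dur") else "time"
        spans.append((m.start(), m.end(), kind))
    taken = [False] * len(text)
    for s, e, _ in spans:
        for i in range(s, e):
            taken[i] = True
    for m in _NUM_UNIT_RE.finditer(text):
        if any(taken[i] for i in range(m.start(), m.end())):
            continue
        spans.append((m.start(), m.end(), "numeral_unit"))
        for i in range(m.start(), m.end()):
            taken[i] = True
    for m in _ASCII_KEY_RE.finditer(text):
        if any(taken[i] for i in range(m.start(), m.end())):
            continue
        spans.append((m.start(), m.end(), "noun"))
    return sorted(spans)


def tokenize(segment, lexicon: Lexicon | None = None) -> list[Token]:
    """Greedy longest-match tokenization of one segment.

    ``segment`` may be a Segment object or a plain string. The token
    surfaces concatenate to exactly the segment text.
    """
    text = segment.text if hasattr(segment, "text") else segment
    if not text:
        raise ValueError("cannot tokenize an empty segment")
    if lexicon is None:
        lexicon = default_lexicon()

    spans = _pattern_spans(text)
    tokens: list[Token] = []
    pos_iter = iter(spans)
    next_span = next(pos_iter, None)
    i = 0
    while i < len(text):
        if next_span is not None and i == next_span[0]:
            s, e, tag = next_span
            tokens.append(Token(text[s:e], tag))
            i = e
            next_span = next(pos_iter, None)
            while next_span is not None and next_span[0] < i:
                next_span = next(pos_iter, None)
            continue
        limit = next_span[0] if next_span is not None else len(text)
        max_k = min(lexicon.max_len, limit - i)
        matched = False
        for k in range(max_k, 0, -1):
            cand = text[i:i + k]
            if cand in lexicon:
                tokens.append(Token(cand, lexicon[cand]))
                i += k
                matched = True
                break
        if not matched:
            ch = text[i]
            if ch in _PUNCT or not (ch.isalnum() or ch == "_"):
                tokens.append(Token(ch, "symbol"))
            else:
                tokens.append(Token(ch, "function"))
            i += 1
    return tokens


def tag_pos(tokens: list[Token], lexicon: Lexicon | None = None
            ) -> list[Token]:
    """Ensure every token carries a POS tag; lexicon tags win, then the
    date / number+unit patterns, then the existing tag."""
    if lexicon is None:
        lexicon = default_lexicon()
    out: list[Token] = []
    for tok in tokens:
        if tok.surface in lexicon:
            out.append(Token(tok.surface, lexicon[tok.surface]))
            continue
        m = _TIME_RE.fullmatch(tok.surface)
        if m:
            out.append(Token(tok.surface,
                             "numeral_unit" if m.group("dur") else "time"))
            continue
        if _NUM_UNIT_RE.fullmatch(tok.surface):
            out.append(Token(tok.surface, "numeral_unit"))
            continue
        out.append(tok)
    return out


def content_tokens(tokens: list[Token]) -> list[Token]:
    """Tokens that carry content (everything but function/symbol)."""
    return [t for t in tokens if t.pos not in ("function", "symbol")]
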