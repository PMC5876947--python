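"""Key-Value extraction of quantified laboratory descriptions.

A lab clause such as 血常规检查：WBC2.13 × 10^9/L, Hb102g/L carries
property-value pairs (K_i, V_i) sharing one descriptive context t (the
examination name). Extraction is lossless: magnitude, power-of-ten
multiplier and unit are copied verbatim from the source — including
malformed units, which are flagged but never silently repaired — so that
re-concatenating an entry's parts reproduces the matched span exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["KVEntry", "KVSet", "extract_kv", "parse_context",
           "is_kv_text", "EXAM_NOUNS"]

#: Examination nouns that may introduce a KV context clause.
EXAM_NOUNS = ("检查", "化验", "测定")

#: Chinese measurement nouns accepted as KV keys.
MEASUREMENT_NOUNS = ("体温", "脉搏", "呼吸", "血压", "心率", "体重", "身高",
                     "血糖", "血氧饱和度")

_KEY_ALT = "|".join(
    [r"[A-Za-z][A-Za-z%]*"] + [re.escape(k) for k in MEASUREMENT_NOUNS])

_KV_RE = re.compile(
    rf"(?P<key>{_KEY_ALT})"
    r"(?P<mag>\d+(?:\.\d+)?)"
    r"(?P<mult>\s*[×x]\s*10\^?(?P<exp>\d+))?"
    r"(?P<unit>[^\s，,。；;：:0-9×][^\s，,。；;：:×]*)?"
)

# a unit ending in a doubled /X component, e.g. /L/L, is flagged
_SUSPECT_UNIT_RE = re.compile(r"(/[A-Za-z]+)\1$")


@dataclass(frozen=True)
class KVEntry:
    """One (K, V)_t property-value pair."""

    i: int  # 1-based order within the KVSet
    key: str
    magnitude: float
    magnitude_text: str  # verbatim numeric text
    multiplier: Optional[str]  # verbatim, e.g. " × 10^9"; None if absent
    exponent: Optional[int]  # 9 for × 10^9; None if absent
    unit: str  # verbatim, possibly empty or malformed
    context: str = ""
    unit_warning: bool = False

    def __post_init__(self) -> None:
        if self.i < 1:
            raise ValueError("entry index i must be >= 1")
        if not self.key:
            raise ValueError("entry key must be nonempty")

    @property
    def source_span_text(self) -> str:
        """Verbatim reconstruction of the matched source span."""
        return f"{self.key}{self.magnitude_text}{self.multiplier or ''}{self.unit}"

    def to_dict(self) -> dict:
        return {
            "i": self.i,
            "key": self.key,
            "magnitude": self.magnitude,
            "multiplier": self.multiplier,
            "unit": self.unit,
            "context": self.context,
        }


@dataclass
class KVSet:
    """The descriptive set D = {KV_t(i)} of one examination clause."""

    entries: list[KVEntry] = field(default_factory=list)
    context: str = ""

    def __post_init__(self) -> None:
        for want, entry in enumerate(self.entries, start=1):
            if entry.i != want:
                raise ValueError("KVSet indices must be contiguous from 1")

    @property
    def n(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def to_dict(self) -> dict:
        return {"context": self.context, "n": self.n,
                "entries": [e.to_dict() for e in self.entries]}


_CONTEXT_PREFIX_RE = re.compile(
    r"^(?:在.{0,8}?(?:我院|医院|院|门诊|急诊))?(?:进行|行|复查|予以|给予|完善)?"
)


def parse_context(introducer_text: str) -> str:
    """Extract the examination name t from a colon-introducer clause.

    在我院进行血常规检查 -> 血常规检查 (location and verb prefixes are
    stripped; the examination noun itself is kept). Returns '' when the
    clause names no examination.
    """
    if not any(nn in introducer_text for nn in EXAM_NOUNS):
        return ""
    return _CONTEXT_PREFIX_RE.sub("", introducer_text)


def extract_kv(segment, context: str = "") -> KVSet:
    """One KVEntry per KEY+NUMBER(+x10^k)(+UNIT) match, in document order.

    ``segment`` may be a Segment object or plain text; text without
    measurement patterns yields an empty KVSet (n=0). The source span of
    each entry is reproduced verbatim by its parts.
    """
    text = segment.text if hasattr(segment, "text") else segment
    entries: list[KVEntry] = []
    for m in _KV_RE.finditer(text):
        unit = m.group("unit") or ""
        entries.append(KVEntry(
            i=len(entries) + 1,
            key=m.group("key"),
            magnitude=float(m.group("mag")),
            magnitude_text=m.group("mag"),
            multiplier=m.group("mult"),
            exponent=int(m.group("exp")) if m.group("exp") else None,
            unit=unit,
            context=context,
            unit_warning=bool(_SUSPECT_UNIT_RE.search(unit)),
        ))
    return KVSet(entries=entries, context=context)


def is_kv_text(text: str) -> bool:
    """True when the text is (only) lab-value matter: every non-space,
    non-delimiter character is covered by a KV match."""
    matches = list(_KV_RE.finditer(text))
    if not matches:
        return False
    covered = [False] * len(text)
    for m in matches:
        for i in range(m.start(), m.end()):
            covered[i] = True
    return all(covered[i] or text[i].isspace() or text[i] in "，,。；;：:."
               for i in range(len(text)))
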