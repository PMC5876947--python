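"""Hierarchical structuring of corrected note text.

A note is split into paragraphs, paragraphs into sentences, sentences into
segments (the comma-delimited clause that is the atomic unit for all later
extraction). The hierarchy is lossless: re-joining the segments with
canonical delimiters reproduces the corrected input up to delimiter
canonicalization and dropped blank spans, and the whole object serializes
to a three-element XML schema (MedicalText/Sentence/Segment).

Delimiter conventions for Chinese clinical narrative:

* sentence delimiters: 。 ． . ！ ？ ； ;  — an ASCII ``.`` between two
  digits is a decimal point (WBC2.13), never a sentence boundary;
* segment delimiters: ， , ： :
* 、 is an in-segment enumeration mark and never splits.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .correction import PARAGRAPH_SEP

__all__ = [
    "Segment",
    "Sentence",
    "MedicalText",
    "SENTENCE_DELIMITERS",
    "SEGMENT_DELIMITERS",
    "structure_text",
    "to_xml",
    "from_xml",
    "reconstruct_text",
    "canonicalize_delimiters",
]

SENTENCE_DELIMITERS = "。．.！？；;"
SEGMENT_DELIMITERS = "，,：:"

# Split points: any sentence delimiter except a '.' flanked by digits.
_SENT_SPLIT = re.compile(r"(?<=\d)\.(?=\d)|([。．.！？；;])")
_SEG_SPLIT = re.compile(r"[，,：:]")


@dataclass(frozen=True)
class Segment:
    """A trimmed, nonempty clause; the atomic extraction unit."""

    text: str
    sentence_index: int
    segment_index: int
    #: Delimiter that followed this segment in the source ('' at clause end).
    trailing_delimiter: str = ""

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("segment text must be nonempty after trimming")
        for ch in self.text:
            if ch in SEGMENT_DELIMITERS:
                raise ValueError(f"segment text contains delimiter {ch!r}")
        # sentence delimiters are forbidden except the decimal '.' case
        for m in re.finditer(r"[。．！？；;]|\.", self.text):
            if m.group() == ".":
                i = m.start()
                if 0 < i < len(self.text) - 1 and self.text[i - 1].isdigit() \
                        and self.text[i + 1].isdigit():
                    continue
                raise ValueError("segment text contains sentence delimiter '.'")
            raise ValueError(
                f"segment text contains sentence delimiter {m.group()!r}")


@dataclass
class Sentence:
    segments: list[Segment] = field(default_factory=list)
    paragraph_index: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a sentence must contain at least one segment")
        for j, seg in enumerate(self.segments):
            if seg.segment_index != j:
                raise ValueError("segment indices must be contiguous from 0")


@dataclass
class MedicalText:
    """The paragraph -> sentence -> segment hierarchy of one note."""

    sentences: list[Sentence] = field(default_factory=list)
    original_text: str = ""

    def __eq__(self, other: object) -> bool:  # structural equality
        if not isinstance(other, MedicalText):
            return NotImplemented
        return [
            [(s.text, s.trailing_delimiter) for s in sent.segments]
            for sent in self.sentences
        ] == [
            [(s.text, s.trailing_delimiter) for s in sent.segments]
            for sent in other.sentences
        ]

    @property
    def n_segments(self) -> int:
        return sum(len(s.segments) for s in self.sentences)

    def iter_segments(self):
        for sent in self.sentences:
            yield from sent.segments


def _split_sentences(paragraph: str) -> list[str]:
    parts: list[str] = []
    i = 0
    for m in _SENT_SPLIT.finditer(paragraph):
        if m.group(1) is None:
            continue  # decimal point, not a boundary
        parts.append(paragraph[i:m.start()])
        i = m.end()
    parts.append(paragraph[i:])
    return parts


def structure_text(text: str) -> MedicalText:
    """Split corrected text into the sentence/segment hierarchy.

    Blank sentences and segments are dropped; a trailing delimiter
    therefore produces no empty trailing node. Indices are assigned in
    document order (sentence indices run across paragraphs).
    """
    sentences: list[Sentence] = []
    si = 0
    for pi, para in enumerate(text.split(PARAGRAPH_SEP)):
        for raw_sent in _split_sentences(para):
            if not raw_sent.strip():
                continue
            segs: list[Segment] = []
            pieces = _SEG_SPLIT.split(raw_sent)
            delims = _SEG_SPLIT.findall(raw_sent)
            gi = 0
            for k, piece in enumerate(pieces):
                if not piece.strip():
                    continue
                segs.append(Segment(
                    text=piece.strip(),
                    sentence_index=si,
                    segment_index=gi,
                    trailing_delimiter=delims[k] if k < len(delims) else "",
                ))
                gi += 1
            if segs:
                sentences.append(Sentence(segments=segs, paragraph_index=pi))
                si += 1
    return MedicalText(sentences=sentences, original_text=text)


def to_xml(mt: MedicalText) -> str:
    """Serialize as UTF-8 XML: MedicalText/Sentence/Segment."""
    root = ET.Element("MedicalText")
    for sent in mt.sentences:
        s_el = ET.SubElement(root, "Sentence",
                             paragraph=str(sent.paragraph_index))
        for seg in sent.segments:
            attrs = {}
            if seg.trailing_delimiter:
                attrs["delim"] = seg.trailing_delimiter
            g_el = ET.SubElement(s_el, "Segment", **attrs)
            g_el.text = seg.text
    body = ET.tostring(root, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body


def from_xml(xml_text: str) -> MedicalText:
    """Parse the XML produced by :func:`to_xml` back into a MedicalText."""
    root = ET.fromstring(xml_text)
    sentences: list[Sentence] = []
    for si, s_el in enumerate(root.findall("Sentence")):
        segs = [
            Segment(
                text=g_el.text or "",
                sentence_index=si,
                segment_index=gi,
                trailing_delimiter=g_el.get("delim", ""),
            )
            for gi, g_el in enumerate(s_el.findall("Segment"))
        ]
        if segs:
            sentences.append(Sentence(
                segments=segs,
                paragraph_index=int(s_el.get("paragraph", "0")),
            ))
    mt = MedicalText(sentences=sentences)
    mt.original_text = reconstruct_text(mt)
    return mt


def reconstruct_text(mt: MedicalText) -> str:
    """Re-join segment texts with their recorded (or canonical) delimiters.

    Equals the corrected input up to dropped blank spans and delimiter
    canonicalization; on delimiter-canonical text structure -> reconstruct
    is the identity.
    """
    prev_para = None
    parts: list[str] = []
    for sent in mt.sentences:
        seg_strs = []
        for k, seg in enumerate(sent.segments):
            seg_strs.append(seg.text)
            if k < len(sent.segments) - 1:
                seg_strs.append(seg.trailing_delimiter or "，")
        body = "".join(seg_strs)
        if prev_para is None:
            parts.append(body)
        elif sent.paragraph_index != prev_para:
            parts.append(PARAGRAPH_SEP + body)
        else:
            parts.append("。" + body)
        prev_para = sent.paragraph_index
    return "".join(parts)


def canonicalize_delimiters(text: str) -> str:
    """Map delimiter variants to canonical 。 and ，, drop blank spans and
    trailing delimiters — the equivalence used by round-trip checks."""
    mt = structure_text(text)
    canonical_parts = []
    prev_para = None
    for sent in mt.sentences:
        body = "，".join(seg.text for seg in sent.segments)
        if prev_para is None:
            canonical_parts.append(body)
        elif sent.paragraph_index != prev_para:
            canonical_parts.append(PARAGRAPH_SEP + body)
        else:
            canonical_parts.append("。" + body)
        prev_para = sent.paragraph_index
    return "".join(canonical_parts)
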