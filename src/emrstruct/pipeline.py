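"""End-to-end orchestration: correct -> structure -> tag -> extract ->
timeline -> entropy, on one note.

Section headers (主诉：/现病史：/…) at the start of a paragraph are
recognized, stripped from the narrative, and carried as context for stage
assignment; time-node inheritance runs within a paragraph (a dated
sentence anchors the undated sentences that follow it) and resets at
paragraph and section boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .config import PipelineConfig
from .correction import PARAGRAPH_SEP, correct_text
from .entropy import EntropyReport, entropy_report
from .kv import KVSet, extract_kv
from .lexicon import Token, tag_pos, tokenize
from .structuring import MedicalText, structure_text
from .ted import TEDDocument, TEDTriple, extract_ted
from .temporal import TimeExpression, extract_time, normalize_time
from .timeline import Timeline, assign_stage, build_timeline

__all__ = ["NoteResult", "process_note", "SECTION_HEADERS"]

SECTION_HEADERS = ("主诉", "现病史", "既往史", "个人史", "家族史",
                   "入院诊断", "出院诊断", "查体", "辅助检查", "诊疗经过",
                   "用药", "医嘱", "出院", "随访", "再次入院", "复诊")

_HEADER_RE = re.compile(
    "^(" + "|".join(re.escape(h) for h in SECTION_HEADERS) + ")[：:]")


@dataclass
class NoteResult:
    """Everything the pipeline derived from one note."""

    raw_text: str
    corrected_text: str  # after header stripping; basis for structuring
    headers: list[Optional[str]]  # per paragraph
    mt: MedicalText
    tokens_by_segment: dict[tuple[int, int], list[Token]]
    times_by_segment: dict[tuple[int, int], list[TimeExpression]]
    kv_by_segment: dict[tuple[int, int], KVSet]
    ted: TEDDocument = field(default_factory=TEDDocument)
    timeline: Timeline = field(default_factory=Timeline)
    entropy: Optional[EntropyReport] = None

    @property
    def triples(self) -> list[TEDTriple]:
        return self.ted.triples

    def all_times(self) -> list[TimeExpression]:
        """Every temporal expression, in document order."""
        return [t for seg in self.mt.iter_segments()
                for t in self.times_by_segment[(seg.sentence_index,
                                                seg.segment_index)]]

    def all_kv_entries(self):
        """Every KV entry attached to a triple, in document order."""
        out = []
        for t in self.triples:
            if isinstance(t.description, KVSet):
                out.extend(t.description.entries)
        return out


def _strip_headers(corrected: str) -> tuple[str, list[Optional[str]]]:
    paragraphs = corrected.split(PARAGRAPH_SEP)
    headers: list[Optional[str]] = []
    stripped: list[str] = []
    for para in paragraphs:
        m = _HEADER_RE.match(para)
        if m:
            headers.append(m.group(1))
            stripped.append(para[m.end():])
        else:
            headers.append(None)
            stripped.append(para)
    return PARAGRAPH_SEP.join(stripped), headers


def process_note(text: str,
                 config: PipelineConfig | None = None,
                 run_entropy: bool = True) -> NoteResult:
    """Run the full pipeline on one note."""
    if config is None:
        config = PipelineConfig()
    corrected_full = correct_text(text, config.rules)
    corrected, headers = _strip_headers(corrected_full)
    mt = structure_text(corrected)

    tokens_by_segment: dict[tuple[int, int], list[Token]] = {}
    times_by_segment: dict[tuple[int, int], list[TimeExpression]] = {}
    kv_by_segment: dict[tuple[int, int], KVSet] = {}
    for seg in mt.iter_segments():
        key = (seg.sentence_index, seg.segment_index)
        tokens_by_segment[key] = tag_pos(tokenize(seg, config.lexicon),
                                         config.lexicon)
        times_by_segment[key] = [
            normalize_time(e, config.reference_date)
            for e in extract_time(seg)
        ]
        kv_by_segment[key] = extract_kv(seg)

    triples: list[TEDTriple] = []
    prev_para: Optional[int] = None
    current: Optional[TimeExpression] = None
    for sentence in mt.sentences:
        if sentence.paragraph_index != prev_para:
            current = None  # inheritance does not cross paragraphs
        prev_para = sentence.paragraph_index
        kvs = [kv_by_segment[(s.sentence_index, s.segment_index)]
               for s in sentence.segments]
        tms = [times_by_segment[(s.sentence_index, s.segment_index)]
               for s in sentence.segments]
        sent_triples = extract_ted(sentence, kvs, tms,
                                   inherited_time=current,
                                   lexicon=config.lexicon)
        header = headers[sentence.paragraph_index] \
            if sentence.paragraph_index < len(headers) else None
        for t in sent_triples:
            t.stage = int(assign_stage(header, t))
        triples.extend(sent_triples)
        non_dur = [t for seg_t in tms for t in seg_t
                   if t.kind != "duration"]
        if non_dur:
            current = non_dur[-1]

    timeline = build_timeline(triples)
    report = None
    if run_entropy:
        report = entropy_report(corrected, mt, tokens_by_segment, timeline,
                                model=config.char_model,
                                weights=config.weights,
                                p_t_mode=config.p_t_mode)
    return NoteResult(
        raw_text=text,
        corrected_text=corrected,
        headers=headers,
        mt=mt,
        tokens_by_segment=tokens_by_segment,
        times_by_segment=times_by_segment,
        kv_by_segment=kv_by_segment,
        ted=TEDDocument(triples=triples),
        timeline=timeline,
        entropy=report,
    )
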