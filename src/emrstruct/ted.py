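"""Time-Event-Description triple extraction.

Each event-bearing segment of a sentence yields one triple (t, e, d):
the time node t is the segment's own date if it contains one, otherwise
the nearest preceding time node (same sentence first, then the
surrounding paragraph — flagged ``inherited``); the event e and
description d come from shallow splitting rules (leading clinical verb,
trailing outcome term); a lab clause contributes its KVSet as d.

An examination introducer ending in a colon (在我院进行血常规检查：...)
forms one event unit with the lab-value spans that follow it: the unit
emits a single triple whose description is the merged KVSet, mirroring
how clinicians read the clause.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .kv import EXAM_NOUNS, KVSet, extract_kv, is_kv_text, parse_context
from .lexicon import Lexicon, default_lexicon, tokenize
from .structuring import Sentence
from .temporal import TimeExpression

__all__ = ["TEDTriple", "TEDDocument", "split_event_description",
           "extract_ted", "OUTCOME_TERMS", "SPLIT_VERBS"]

#: Outcome/evaluation terms that close an event clause.
OUTCOME_TERMS = ("未见异常", "明显好转", "无效", "有效", "好转", "缓解",
                 "加重", "正常")

#: Verbs that, when leading a clause, are themselves the event.
SPLIT_VERBS = ("出现", "诉", "给予", "行", "进行", "否认")

_LOCATION_PREFIX_RE = re.compile(
    r"^(?:在.{0,8}?(?:我院|医院|院|门诊|急诊))")


@dataclass
class TEDTriple:
    """One (time, event, description) record."""

    time: Optional[TimeExpression]
    event: str
    description: Union[str, KVSet, None]
    source: tuple[int, int]  # (sentence_index, segment_index)
    inherited: bool = False
    duration: Optional[TimeExpression] = None
    stage: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.event:
            raise ValueError("triple event must be nonempty")

    @property
    def time_key(self) -> Optional[str]:
        """Normalized time string used for timeline grouping."""
        if self.time is None:
            return None
        if self.time.is_resolved_date:
            return self.time.normalized
        return self.time.raw  # unresolved relative: group by surface form

    def to_dict(self) -> dict:
        kv = self.description if isinstance(self.description, KVSet) else None
        return {
            "time": self.time_key,
            "granularity": self.time.granularity if self.time else None,
            "inherited": self.inherited,
            "event": self.event,
            "description": (self.description
                            if isinstance(self.description, str)
                            else None),
            "kv": [e.to_dict() for e in kv] if kv is not None else None,
            "sentence": self.source[0],
            "segment": self.source[1],
        }


@dataclass
class TEDDocument:
    """All triples of one note, in document order."""

    triples: list[TEDTriple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def to_dict(self) -> dict:
        return {"triples": [t.to_dict() for t in self.triples]}


def split_event_description(segment_text: str) -> tuple[str, str]:
    """Split an event clause into (event, description).

    A trailing outcome term is the description (给予阿奇霉素抗感染无效 ->
    event 给予阿奇霉素抗感染, description 无效); otherwise a leading
    clinical verb is the event and the remainder the description
    (出现咽痛 -> 出现, 咽痛); otherwise the whole clause is the event.
    """
    for term in OUTCOME_TERMS:
        if segment_text.endswith(term) and len(segment_text) > len(term):
            return segment_text[: -len(term)], term
    for verb in SPLIT_VERBS:
        if segment_text.startswith(verb) and len(segment_text) > len(verb):
            return verb, segment_text[len(verb):]
    return segment_text, ""


def _strip_leading_time(text: str, times: list[TimeExpression]) -> str:
    """Remove a time expression sitting at the start of the clause (plus a
    following enumeration mark) so the event split sees the clause body."""
    for expr in times:
        if expr.kind == "duration":
            continue
        if expr.span[0] == 0:
            rest = text[expr.span[1]:]
            return rest.lstrip("、 ")
    return text


def _is_event_bearing(text: str, kvset: KVSet,
                      times: list[TimeExpression],
                      lexicon: Lexicon) -> bool:
    if kvset:
        return True
    if any(term in text for term in OUTCOME_TERMS):
        return True
    # a dated mention with residual content is an event (1月头痛)
    has_date = any(t.kind != "duration" for t in times)
    if has_date and _strip_leading_time(text, times):
        return True
    toks = tokenize(text, lexicon)
    return any(t.pos in ("verb", "negation") for t in toks)


def _is_pure_time(text: str, times: list[TimeExpression]) -> bool:
    covered = [False] * len(text)
    for expr in times:
        if expr.kind == "duration":
            continue
        for i in range(*expr.span):
            covered[i] = True
    return bool(times) and all(
        covered[i] or not text[i].strip() or text[i] in "、"
        for i in range(len(text)))


def extract_ted(sentence: Sentence,
                kv_sets: list[KVSet],
                times: list[list[TimeExpression]],
                inherited_time: Optional[TimeExpression] = None,
                lexicon: Lexicon | None = None) -> list[TEDTriple]:
    """Build the TED triples of one sentence.

    ``kv_sets`` and ``times`` are per-segment extraction results aligned
    with ``sentence.segments``. Pure time-stamp segments set the running
    time node and emit no triple; an exam introducer absorbs following
    lab-value segments into one triple with a merged KVSet; other
    event-bearing segments emit one triple each. Sentences with no time
    node anywhere still emit triples (time=None), never silently dropped.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    triples: list[TEDTriple] = []
    current: Optional[TimeExpression] = inherited_time
    open_kv_triple: Optional[TEDTriple] = None

    for seg, kvset, seg_times in zip(sentence.segments, kv_sets, times):
        non_dur = [t for t in seg_times if t.kind != "duration"]
        durations = [t for t in seg_times if t.kind == "duration"]

        if _is_pure_time(seg.text, seg_times):
            current = non_dur[0]
            open_kv_triple = None
            continue

        # lab-value continuation of an open exam introducer
        if is_kv_text(seg.text) and open_kv_triple is not None:
            merged = open_kv_triple.description
            assert isinstance(merged, KVSet)
            for entry in extract_kv(seg.text, merged.context):
                merged.entries.append(
                    type(entry)(**{**entry.__dict__,
                                   "i": len(merged.entries) + 1}))
            continue

        if not _is_event_bearing(seg.text, kvset, seg_times, lexicon):
            open_kv_triple = None
            continue

        own_time = non_dur[0] if non_dur else None
        time = own_time if own_time is not None else current
        inherited = own_time is None and time is not None

        body = _strip_leading_time(seg.text, seg_times)
        is_introducer = (any(nn in seg.text for nn in EXAM_NOUNS)
                         and seg.trailing_delimiter in ("：", ":"))
        if is_introducer:
            event = _LOCATION_PREFIX_RE.sub("", body)
            context = parse_context(seg.text)
            description: Union[str, KVSet] = KVSet(entries=[],
                                                   context=context)
        elif kvset:
            event, _ = split_event_description(body)
            description = kvset
        else:
            event, description = split_event_description(body)

        triple = TEDTriple(
            time=time,
            event=event or seg.text,
            description=description,
            source=(seg.sentence_index, seg.segment_index),
            inherited=inherited,
            duration=durations[0] if durations else None,
        )
        triples.append(triple)
        open_kv_triple = triple if is_introducer else None

        if own_time is not None:
            current = own_time
    return triples
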