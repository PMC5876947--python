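"""Shannon-entropy evaluation of the structuring phases.

The uncertainty of a note is measured under a uniform character model
(N distinct characters in common clinical use, default 2500) and
recomputed after each structuring phase:

* phase 0 (raw text): every character is an independent draw from the
  N-ary alphabet — log2 N bits per character, L·log2 N in total.
* phase I (sentence/segment splitting): each segment is one draw whose
  identification cost, −Σ p log2 p = log2 N under the uniform model, is
  spread over its n_j characters; sentence entropies are the sum of
  their segments' per-character costs and the note value is the mean
  over sentences:  H = (1/m) Σ_i Σ_j (−Σ p log2 p) / n_j.
* phase II (POS tagging): a segment's c terms form a probability
  distribution — term w gets base mass weight(pos)·(1/N)^{n_w}
  (longer terms are rarer, important parts of speech more likely),
  renormalized within the segment — and contributes its term entropy
  H_s = −Σ p(w) log2 p(w) per term, aggregated exactly like phase I
  with terms in place of characters.
* phase III (temporal structuring): triples attach to time nodes; each
  resolved calendar anchor is given, not decoded, and absorbs
  probability mass R/(R+1) (R = resolved node count) from its attached
  segments' term distributions, leaving residual entropy H_s/(1+R);
  the timeline entropy is the convex combination H_tl = Σ_t p_t H_s(t)
  with p_t the node's share of triples (or uniform, by configuration).

All logarithms are base 2; every value is in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .lexicon import POSWeightTable, Token, default_weights
from .structuring import MedicalText
from .timeline import Timeline, _sort_date

__all__ = [
    "CharModel",
    "RawEntropy",
    "EntropyInput",
    "TaggedSegment",
    "EntropyReport",
    "entropy_raw",
    "entropy_structured",
    "term_probability",
    "segment_distribution",
    "segment_entropy",
    "entropy_tagged",
    "node_entropy",
    "entropy_temporal",
    "entropy_report",
]


@dataclass(frozen=True)
class CharModel:
    """Uniform character model over an N-character alphabet."""

    alphabet_size: int = 2500

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValueError("alphabet size must be >= 2")

    @property
    def p_char(self) -> float:
        return 1.0 / self.alphabet_size

    @property
    def bits_per_char(self) -> float:
        return math.log2(self.alphabet_size)


@dataclass(frozen=True)
class RawEntropy:
    total: float
    per_char: float
    n_chars: int


def entropy_raw(text: str, model: CharModel = CharModel()) -> RawEntropy:
    """Uncertainty of unstructured text: L·log2 N total, log2 N per char."""
    length = len(text)
    if length == 0:
        return RawEntropy(0.0, 0.0, 0)
    per_char = model.bits_per_char
    return RawEntropy(length * per_char, per_char, length)


def _dist_entropy(p: Union[float, Sequence[float]]) -> float:
    """Entropy in bits of a word distribution given either the uniform
    per-word probability (scalar) or an explicit probability vector."""
    if isinstance(p, (int, float)):
        if not 0 < p <= 1:
            raise ValueError("uniform probability must be in (0, 1]")
        return -math.log2(p)
    total = math.fsum(p)
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("probability vector must sum to 1")
    return -math.fsum(x * math.log2(x) for x in p if x > 0)


@dataclass
class EntropyInput:
    """Phase-I summary of a structured note.

    ``sentences`` holds, per sentence, the list of (n_j, p_j) pairs for
    its segments: n_j the word (character) count and p_j either the
    uniform word probability or an explicit distribution.
    """

    sentences: list[list[tuple[int, Union[float, Sequence[float]]]]]

    def __post_init__(self) -> None:
        for segs in self.sentences:
            for n_j, _ in segs:
                if n_j < 1:
                    raise ValueError("segment word count n_j must be >= 1")

    @classmethod
    def from_medical_text(cls, mt: MedicalText,
                          model: CharModel = CharModel()) -> "EntropyInput":
        return cls(sentences=[
            [(len(seg.text), model.p_char) for seg in sent.segments]
            for sent in mt.sentences
        ])


def entropy_structured(inp: EntropyInput) -> float:
    """Phase-I entropy: mean over sentences of the segment costs
    (−Σ p log2 p)/n_j. Empty input yields 0."""
    m = len(inp.sentences)
    if m == 0:
        return 0.0
    total = 0.0
    for segs in inp.sentences:
        total += math.fsum(_dist_entropy(p) / n_j for n_j, p in segs)
    return total / m


def term_probability(token: Token, model: CharModel = CharModel(),
                     weights: POSWeightTable | None = None) -> float:
    """Unnormalized base mass of one term: weight(pos)·(1/N)^{n_w}."""
    if weights is None:
        weights = default_weights()
    return weights[token.pos] * model.p_char ** token.n_w


def segment_distribution(tokens: Sequence[Token],
                         model: CharModel = CharModel(),
                         weights: POSWeightTable | None = None
                         ) -> list[float]:
    """Per-segment renormalized term probabilities (sum to 1)."""
    if not tokens:
        return []
    base = [term_probability(t, model, weights) for t in tokens]
    z = math.fsum(base)
    return [b / z for b in base]


def segment_entropy(tokens: Sequence[Token],
                    model: CharModel = CharModel(),
                    weights: POSWeightTable | None = None) -> float:
    """H_s of one tagged segment: −Σ p(w) log2 p(w) over its c terms."""
    p = segment_distribution(tokens, model, weights)
    return -math.fsum(x * math.log2(x) for x in p if x > 0)


@dataclass
class TaggedSegment:
    """Phase-II view of one segment: its tagged terms."""

    tokens: list[Token]
    sentence_index: int = 0

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("a tagged segment must contain >= 1 term")

    @property
    def c(self) -> int:
        return len(self.tokens)


def entropy_tagged(segments: Sequence[TaggedSegment],
                   model: CharModel = CharModel(),
                   weights: POSWeightTable | None = None) -> float:
    """Phase-II entropy: segment term entropies H_s, spread over the c
    terms of each segment and averaged over sentences (the phase-I
    aggregation with terms in place of characters)."""
    if not segments:
        return 0.0
    by_sentence: dict[int, list[TaggedSegment]] = {}
    for seg in segments:
        by_sentence.setdefault(seg.sentence_index, []).append(seg)
    total = 0.0
    for segs in by_sentence.values():
        total += math.fsum(
            segment_entropy(s.tokens, model, weights) / s.c for s in segs)
    return total / len(by_sentence)


def node_entropy(segment_values: Sequence[float], resolved: bool,
                 n_resolved: int) -> float:
    """H_s(t): mean per-term entropy of the node's attached segments,
    discounted by the temporal grounding factor 1/(1+R) when the node is
    anchored at a resolved calendar date (R = resolved node count)."""
    if not segment_values:
        return 0.0
    mean = math.fsum(segment_values) / len(segment_values)
    if resolved:
        return mean / (1 + n_resolved)
    return mean


def entropy_temporal(node_entropies: Sequence[float],
                     node_triple_counts: Sequence[int],
                     p_t_mode: str = "share") -> float:
    """Phase-III entropy H_tl = Σ_t p_t H_s(t).

    ``p_t`` is each node's share of attached triples (default) or
    uniform 1/T. Empty timeline yields 0.
    """
    if len(node_entropies) != len(node_triple_counts):
        raise ValueError("node entropies and triple counts must align")
    if not node_entropies:
        return 0.0
    if p_t_mode == "uniform":
        p = [1.0 / len(node_entropies)] * len(node_entropies)
    elif p_t_mode == "share":
        total = sum(node_triple_counts)
        if total == 0:
            return 0.0
        p = [c / total for c in node_triple_counts]
    else:
        raise ValueError(f"unknown p_t mode {p_t_mode!r}")
    return math.fsum(w * h for w, h in zip(p, node_entropies))


@dataclass
class EntropyReport:
    """H values (bits) for the raw text and the three phases."""

    h_raw_total: float
    h_raw_per_char: float
    h_phase1: float
    h_phase2: float
    h_phase3: float
    node_entropies: list[float] = field(default_factory=list)
    node_weights: list[float] = field(default_factory=list)
    monotone: bool = True
    violations: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "h_raw_total": round(self.h_raw_total, 6),
            "h_raw_per_char": round(self.h_raw_per_char, 6),
            "h_phase1": round(self.h_phase1, 6),
            "h_phase2": round(self.h_phase2, 6),
            "h_phase3": round(self.h_phase3, 6),
            "node_entropies": [round(h, 6) for h in self.node_entropies],
            "node_weights": [round(w, 6) for w in self.node_weights],
            "monotone": self.monotone,
            "violations": self.violations,
        }


def entropy_report(text: str,
                   mt: MedicalText,
                   tokens_by_segment: dict[tuple[int, int], list[Token]],
                   timeline: Optional[Timeline],
                   model: CharModel = CharModel(),
                   weights: POSWeightTable | None = None,
                   p_t_mode: str = "share") -> EntropyReport:
    """Full per-note entropy summary with phase-ordering diagnostics."""
    raw = entropy_raw(text, model)
    h1 = entropy_structured(EntropyInput.from_medical_text(mt, model))

    tagged = [
        TaggedSegment(tokens=tokens_by_segment[(seg.sentence_index,
                                                seg.segment_index)],
                      sentence_index=seg.sentence_index)
        for seg in mt.iter_segments()
        if tokens_by_segment.get((seg.sentence_index, seg.segment_index))
    ]
    h2 = entropy_tagged(tagged, model, weights)

    h2_by_segment = {
        (seg.sentence_index, seg.segment_index):
            segment_entropy(toks, model, weights) / len(toks)
        for seg in mt.iter_segments()
        if (toks := tokens_by_segment.get((seg.sentence_index,
                                           seg.segment_index)))
    }

    node_hs: list[float] = []
    node_counts: list[int] = []
    if timeline is not None and len(timeline) > 0:
        n_resolved = timeline.n_resolved
        for node in timeline:
            sources = []
            seen = set()
            for t in node.triples:
                if t.source not in seen and t.source in h2_by_segment:
                    sources.append(h2_by_segment[t.source])
                    seen.add(t.source)
            resolved = _sort_date(node.time) is not None
            node_hs.append(node_entropy(sources, resolved, n_resolved))
            node_counts.append(len(node.triples))
        h3 = entropy_temporal(node_hs, node_counts, p_t_mode)
        total = sum(node_counts)
        if p_t_mode == "uniform":
            node_w = [1.0 / len(node_hs)] * len(node_hs)
        else:
            node_w = [c / total for c in node_counts] if total else []
    else:
        h3 = 0.0
        node_w = []

    violations = []
    tol = 1e-9
    if h1 > raw.per_char + tol and raw.n_chars > 0:
        violations.append("h_phase1 > h_raw_per_char")
    if h2 > h1 + tol:
        violations.append("h_phase2 > h_phase1")
    if h3 > h2 + tol:
        violations.append("h_phase3 > h_phase2")

    return EntropyReport(
        h_raw_total=raw.total,
        h_raw_per_char=raw.per_char,
        h_phase1=h1,
        h_phase2=h2,
        h_phase3=h3,
        node_entropies=node_hs,
        node_weights=node_w,
        monotone=not violations,
        violations=violations,
    )
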