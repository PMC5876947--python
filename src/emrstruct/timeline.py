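"""Patient-condition timeline assembly.

Triples are mapped onto the six-stage course of an admission —
1 healthy status, 2 hospital diagnosis, 3 treatment process, 4 medical
treatment, 5 clinical follow-up, 6 return visit — and grouped into
time-ordered nodes. Stage assignment is a deterministic keyword map:
the EMR section header decides when present, otherwise verb cues in the
event text, with treatment-process (3) as the default. Ordering is
granularity-aware: a month-granularity date sorts at its first day and a
year at January 1; unresolved or missing times sort after all dated
nodes in document order. Durations (20年) never create nodes — they ride
on their triples as attributes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

from .ted import TEDTriple

__all__ = ["TDMStage", "TimelineNode", "Timeline", "assign_stage",
           "build_timeline"]


class TDMStage(IntEnum):
    HEALTHY_STATUS = 1
    HOSPITAL_DIAGNOSIS = 2
    TREATMENT_PROCESS = 3
    MEDICAL_TREATMENT = 4
    CLINICAL_FOLLOW_UP = 5
    RETURN_VISIT = 6


# Header keywords, checked in order; first substring hit wins. More
# specific headers precede their substrings (再次入院 before 入院诊断).
_HEADER_STAGES: tuple[tuple[str, TDMStage], ...] = (
    ("再次入院", TDMStage.RETURN_VISIT),
    ("复诊", TDMStage.RETURN_VISIT),
    ("出院", TDMStage.CLINICAL_FOLLOW_UP),
    ("随访", TDMStage.CLINICAL_FOLLOW_UP),
    ("入院诊断", TDMStage.HOSPITAL_DIAGNOSIS),
    ("查体", TDMStage.HOSPITAL_DIAGNOSIS),
    ("辅助检查", TDMStage.HOSPITAL_DIAGNOSIS),
    ("诊疗经过", TDMStage.TREATMENT_PROCESS),
    ("用药", TDMStage.MEDICAL_TREATMENT),
    ("医嘱", TDMStage.MEDICAL_TREATMENT),
    ("治疗", TDMStage.MEDICAL_TREATMENT),
    ("主诉", TDMStage.HEALTHY_STATUS),
    ("现病史", TDMStage.HEALTHY_STATUS),
    ("既往史", TDMStage.HEALTHY_STATUS),
    ("个人史", TDMStage.HEALTHY_STATUS),
    ("家族史", TDMStage.HEALTHY_STATUS),
)

# Verb cues in the event text when no header is available. Leading-verb
# cues must open the event (行 would otherwise fire inside 进行);
# substring cues may sit anywhere.
_PREFIX_VERB_STAGES: tuple[tuple[str, TDMStage], ...] = (
    ("给予", TDMStage.MEDICAL_TREATMENT),
    ("予", TDMStage.MEDICAL_TREATMENT),
    ("行", TDMStage.MEDICAL_TREATMENT),
    ("服用", TDMStage.MEDICAL_TREATMENT),
)
_VERB_STAGES: tuple[tuple[str, TDMStage], ...] = (
    ("治疗", TDMStage.MEDICAL_TREATMENT),
    ("随访", TDMStage.CLINICAL_FOLLOW_UP),
    ("诊断", TDMStage.HOSPITAL_DIAGNOSIS),
    ("检查", TDMStage.HOSPITAL_DIAGNOSIS),
    ("化验", TDMStage.HOSPITAL_DIAGNOSIS),
)


def assign_stage(section_header: Optional[str],
                 triple: TEDTriple) -> TDMStage:
    """Deterministic stage for one triple; total (never raises)."""
    if section_header:
        for key, stage in _HEADER_STAGES:
            if key in section_header:
                return stage
    for key, stage in _PREFIX_VERB_STAGES:
        if triple.event.startswith(key):
            return stage
    for key, stage in _VERB_STAGES:
        if key in triple.event:
            return stage
    return TDMStage.TREATMENT_PROCESS


@dataclass
class TimelineNode:
    time: Optional[str]  # normalized date, raw relative form, or None
    stage: TDMStage
    triples: list[TEDTriple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "stage": int(self.stage),
            "triples": [t.to_dict() for t in self.triples],
        }


@dataclass
class Timeline:
    nodes: list[TimelineNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    @property
    def n_triples(self) -> int:
        return sum(len(n.triples) for n in self.nodes)

    @property
    def n_resolved(self) -> int:
        """Nodes anchored at a resolved calendar date."""
        return sum(1 for n in self.nodes if _sort_date(n.time) is not None)

    def to_dict(self) -> dict:
        return {"nodes": [n.to_dict() for n in self.nodes]}

    def to_tsv(self) -> str:
        lines = ["time\tstage\tevent\tdescription"]
        for node in self.nodes:
            for t in node.triples:
                desc = t.to_dict()
                d = desc["description"] if desc["description"] is not None \
                    else (f"[KV n={len(desc['kv'])}]"
                          if desc["kv"] is not None else "")
                stage = t.stage if t.stage is not None else int(node.stage)
                lines.append(f"{node.time or ''}\t{stage}\t"
                             f"{t.event}\t{d}")
        return "\n".join(lines) + "\n"


def _sort_date(key: Optional[str]) -> Optional[dt.date]:
    """Earliest possible instant of a normalized date string, else None."""
    if key is None:
        return None
    parts = key.split("-")
    try:
        nums = [int(p) for p in parts]
    except ValueError:
        return None
    if len(nums) == 1:
        return dt.date(nums[0], 1, 1)
    if len(nums) == 2:
        return dt.date(nums[0], nums[1], 1)
    return dt.date(nums[0], nums[1], nums[2])


def build_timeline(triples: list[TEDTriple]) -> Timeline:
    """Group triples by time node and sort nodes chronologically.

    Stages must already be assigned (unstaged triples default to the
    treatment process). Dated nodes sort by their earliest possible
    instant, coarser granularity first on ties; unresolved and missing
    times follow in document order. Every triple lands in exactly one
    node; within a node, document order is preserved.
    """
    groups: dict[Optional[str], list[TEDTriple]] = {}
    order: list[Optional[str]] = []
    for t in triples:
        key = t.time_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(t)

    def node_key(key: Optional[str]):
        d = _sort_date(key)
        if d is not None:
            return (0, d.toordinal(), len(key), 0)
        # unresolved relative or absent time: document order, after dates
        return (1, 0, 0, order.index(key))

    nodes = []
    for key in sorted(order, key=node_key):
        group = groups[key]
        stage = group[0].stage if group[0].stage is not None \
            else TDMStage.TREATMENT_PROCESS
        nodes.append(TimelineNode(time=key, stage=TDMStage(stage),
                                  triples=group))
    return Timeline(nodes=nodes)
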