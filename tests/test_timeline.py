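"""Stage assignment and granularity-aware timeline ordering."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrstruct.ted import TEDTriple
from emrstruct.temporal import TimeExpression
from emrstruct.timeline import TDMStage, assign_stage, build_timeline


def _triple(event="出现", time_key=None, granularity="day", stage=None,
            source=(0, 0)):
    time = None
    if time_key is not None:
        time = TimeExpression(raw=time_key, span=(0, len(time_key)),
                              kind="absolute_date", normalized=time_key,
                              granularity=granularity)
    return TEDTriple(time=time, event=event, description="",
                     source=source, stage=stage)


class TestAssignStage:
    @pytest.mark.parametrize("header,expected", [
        ("既往史", TDMStage.HEALTHY_STATUS),
        ("主诉", TDMStage.HEALTHY_STATUS),
        ("入院诊断", TDMStage.HOSPITAL_DIAGNOSIS),
        ("诊疗经过", TDMStage.TREATMENT_PROCESS),
        ("用药", TDMStage.MEDICAL_TREATMENT),
        ("出院", TDMStage.CLINICAL_FOLLOW_UP),
        ("再次入院", TDMStage.RETURN_VISIT),
    ])
    def test_header_keywords_decide(self, header, expected):
        assert assign_stage(header, _triple()) == expected

    @pytest.mark.parametrize("event,expected", [
        ("给予阿奇霉素抗感染", TDMStage.MEDICAL_TREATMENT),
        ("行胸片", TDMStage.MEDICAL_TREATMENT),
        ("进行血常规检查", TDMStage.HOSPITAL_DIAGNOSIS),
        ("门诊随访", TDMStage.CLINICAL_FOLLOW_UP),
        ("出现", TDMStage.TREATMENT_PROCESS),
    ])
    def test_verb_cues_without_header(self, event, expected):
        assert assign_stage(None, _triple(event=event)) == expected

    def test_header_wins_over_verb_cue(self):
        t = _triple(event="给予阿奇霉素抗感染")
        assert assign_stage("既往史", t) == TDMStage.HEALTHY_STATUS

    def test_default_is_treatment_process(self):
        assert assign_stage(None, _triple(event="咽痛")) \
            == TDMStage.TREATMENT_PROCESS


class TestBuildTimeline:
    def test_shared_date_collapses_to_single_node(self):
        triples = [_triple(time_key="2008-03-11", source=(0, i))
                   for i in range(3)]
        tl = build_timeline(triples)
        assert len(tl) == 1
        assert tl.nodes[0].time == "2008-03-11"
        assert len(tl.nodes[0].triples) == 3

    def test_empty_input_gives_empty_timeline(self):
        tl = build_timeline([])
        assert len(tl) == 0 and tl.n_triples == 0

    def test_granularity_aware_ordering(self):
        triples = [
            _triple(time_key="2008-03", granularity="month", source=(0, 0)),
            _triple(time_key="2008-03-11", source=(1, 0)),
            _triple(time_key="2007", granularity="year", source=(2, 0)),
        ]
        tl = build_timeline(triples)
        assert [n.time for n in tl.nodes] == ["2007", "2008-03",
                                              "2008-03-11"]

    def test_untimed_triples_group_after_dated_nodes(self):
        triples = [_triple(source=(0, 0)),
                   _triple(time_key="2008-03-11", source=(1, 0)),
                   _triple(source=(2, 0))]
        tl = build_timeline(triples)
        assert [n.time for n in tl.nodes] == ["2008-03-11", None]
        assert len(tl.nodes[1].triples) == 2

    def test_unresolved_relative_forms_grouped_by_surface(self):
        rel = TimeExpression(raw="3天前", span=(0, 3), kind="relative",
                             magnitude=3.0, unit="day", direction=-1)
        triples = [TEDTriple(time=rel, event="出现", description="",
                             source=(0, 0)),
                   _triple(time_key="2008-03-11", source=(1, 0))]
        tl = build_timeline(triples)
        assert [n.time for n in tl.nodes] == ["2008-03-11", "3天前"]

    def test_conservation_of_triples(self):
        triples = [_triple(time_key=k, source=(i, 0)) for i, k in enumerate(
            ["2008-03-11", "2007", "2008-03-11", None, "2009-01-02"])]
        tl = build_timeline(triples)
        assert tl.n_triples == len(triples)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.one_of(
        st.none(),
        st.dates(min_value=dt.date(2000, 1, 1),
                 max_value=dt.date(2020, 12, 31)).map(str)),
        max_size=12))
    def test_sorting_is_total_stable_and_conserving(self, keys):
        triples = [_triple(time_key=k, source=(i, 0))
                   for i, k in enumerate(keys)]
        tl = build_timeline(triples)
        assert tl.n_triples == len(triples)
        dated = [n.time for n in tl.nodes if n.time is not None]
        assert dated == sorted(dated)
        for node in tl.nodes:  # document order within a node
            sources = [t.source for t in node.triples]
            assert sources == sorted(sources)
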