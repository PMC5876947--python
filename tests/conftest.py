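"""Shared fixtures: worked-example sentences and a default pipeline config."""

import pytest

from emrstruct import PipelineConfig

#: Dated event chain with a blood-routine lab panel (onset, treatment,
#: examination with three analytes).
BLOOD_ROUTINE_NOTE = (
    "2008年3月11日出现咽痛，给予阿奇霉素抗感染无效，"
    "在我院进行血常规检查：WBC2.13 × 10^9/L, Hb102g/L, PLT177 × 10^9/L/L."
)

#: Negated past-history enumeration with duration mentions.
HISTORY_SENTENCE = "否认肝炎、结核、疟疾病史，高血压史、冠心病史20年，糖尿病史20年"

#: The seven content phrases of the first two history clauses.
HISTORY_PHRASES = ["否认", "肝炎", "结核", "疟疾病", "高血压", "冠心病", "20年"]


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def blood_routine_note() -> str:
    return BLOOD_ROUTINE_NOTE


@pytest.fixture(scope="session")
def history_sentence() -> str:
    return HISTORY_SENTENCE
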