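"""Pipeline configuration: packaged defaults, YAML overrides, CLI flags."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .correction import RuleSet, default_rules, load_rules
from .entropy import CharModel
from .lexicon import Lexicon, POSWeightTable, default_lexicon, load_lexicon

__all__ = ["PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Raised for a malformed configuration file or value."""


@dataclass
class PipelineConfig:
    rules: RuleSet = field(default_factory=default_rules)
    lexicon: Lexicon = field(default_factory=default_lexicon)
    weights: POSWeightTable = field(default_factory=POSWeightTable)
    alphabet_size: int = 2500
    p_t_mode: str = "share"
    reference_date: Optional[str] = None

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ConfigError("alphabet_size must be >= 2")
        if self.p_t_mode not in ("share", "uniform"):
            raise ConfigError("p_t_mode must be 'share' or 'uniform'")

    @property
    def char_model(self) -> CharModel:
        return CharModel(alphabet_size=self.alphabet_size)


def _packaged_defaults() -> dict:
    ref = resources.files("emrstruct.data").joinpath("default_config.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def load_config(yaml_path: str | Path | None = None,
                rule_path: str | Path | None = None,
                lexicon_path: str | Path | None = None,
                **overrides) -> PipelineConfig:
    """Build a config with precedence flag > YAML > packaged default."""
    data = _packaged_defaults()
    if yaml_path is not None:
        p = Path(yaml_path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            user = yaml.safe_load(p.read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {p}: {exc}") from exc
        if not isinstance(user, dict):
            raise ConfigError(f"config file {p} must contain a mapping")
        data.update(user)
    data.update({k: v for k, v in overrides.items() if v is not None})

    weights = POSWeightTable(weights=dict(data["pos_weights"])) \
        if "pos_weights" in data else POSWeightTable()
    try:
        return PipelineConfig(
            rules=load_rules(rule_path) if rule_path else default_rules(),
            lexicon=(load_lexicon(lexicon_path) if lexicon_path
                     else default_lexicon()),
            weights=weights,
            alphabet_size=int(data.get("alphabet_size", 2500)),
            p_t_mode=str(data.get("p_t_mode", "share")),
            reference_date=data.get("reference_date"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
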