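# Default pipeline configuration. CLI flags override these values.

# Uniform character model: number of distinct Chinese characters assumed
# in common clinical use.
alphabet_size: 2500

# Part-of-speech importance weights used when scaling term probabilities.
# Only the ordering matters for the qualitative entropy trends; the noun
# weight must exceed the function-word weight.
pos_weights:
  noun: 0.30
  verb: 0.20
  time: 0.20
  numeral_unit: 0.15
  adjective: 0.08
  negation: 0.04
  function: 0.02
  symbol: 0.01

# Weighting of time nodes in the timeline entropy: "share" weights each
# node by its share of attached triples; "uniform" gives each node 1/T.
p_t_mode: share

# Reference date (ISO) used to resolve relative expressions such as 3天前;
# null leaves them unresolved.
reference_date: null

# Delimiter inventories used by the structuring stage (audit only; the
# structuring rules compile these same sets).
sentence_delimiters: ["。", "．", ".", "！", "？", "；", ";"]
segment_delimiters: ["，", ",", "：", ":"]

# Temporal patterns recognized by the rule-based extractor (audit list).
temporal_patterns:
  - "YYYY年M月D日"
  - "YYYY年M月"
  - "YYYY年"
  - "YYYY-M-D"
  - "M月D日"
  - "N{年|个月|月|周|天|日|小时}[前|后|来]"
  - "今天|昨天|前天|今年|去年"
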