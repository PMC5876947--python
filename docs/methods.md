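# Methods

This note documents the models, rules and numerical choices behind
`emrstruct`, in the order the pipeline applies them, together with the
assumptions each stage makes and the limits of what the synthetic
evaluation can show.

## Text correction

Correction is an ordered table of literal substitutions applied after an
artefact sweep. The sweep removes zero-width/BOM characters, deletes
single hard line wraps (CJK text carries no inter-word spaces, so joining
is lossless), and maps runs of blank lines to U+2029 PARAGRAPH SEPARATOR.
That last choice reconciles two contracts: corrected text must be free of
newline/carriage-return characters, yet paragraph structure must survive
for section handling; U+2029 is the one standard separator satisfying
both. Rules then apply sequentially — each as a global, leftmost,
non-overlapping literal replacement — so later rules see earlier rules'
output. Interior single spaces are preserved: collapsing them would
destroy token boundaries inside lab expressions (`2.13 × 10^9/L`).
The packaged table folds full-width digits/letters to ASCII and fixes a
few recurring variant characters; it is illustrative, since every
hospital maintains its own table.

## Structuring

Sentence delimiters are 。 ． . ！ ？ ； ; and segment delimiters
， , ： : — the full-width inventory of Chinese clinical punctuation plus
their ASCII forms. Two deliberate exceptions:

* an ASCII `.` flanked by digits is a decimal point, never a sentence
  boundary (otherwise `WBC2.13` would split);
* 、 is an in-segment enumeration mark: 否认肝炎、结核、疟疾病史 is one
  clause, not three.

Blank spans are dropped, so trailing delimiters produce no empty nodes.
Each segment records the delimiter that followed it, which lets
`reconstruct_text` re-join the hierarchy to the corrected input exactly
(up to delimiter canonicalization) and lets the extraction stage
recognize colon-introduced examination clauses. Paragraph indices are
carried on sentences but do not enter the entropy equations.

## Tokenization and POS

No statistical tagger is used: the domain is closed enough that greedy
longest-match over a ~160-entry clinical lexicon is deterministic,
auditable and exact on the covered vocabulary. Temporal expressions and
number+unit readings are matched first (so 2008年3月11日 and
`2.13 × 10^9/L` stay atomic), then the lexicon, then single-character
fallback (`function` for unknown CJK, `symbol` for punctuation) — never
an exception, and token surfaces always concatenate to the segment.
History suffixes (史/病史) are function morphemes, which reproduces the
reference phrase split 否认|肝炎|结核|疟疾病|高血压|冠心病|20年.

POS weights (noun 0.30, verb 0.20, time 0.20, numeral_unit 0.15,
adjective 0.08, negation 0.04, function 0.02, symbol 0.01) encode
relative importance for the entropy model. Only the ordering
noun > function is substantive; the numeric values are a package default
and configurable.

## Temporal expressions

The extractor is a fixed, ordered alternation: YYYY年M月D日, YYYY-M-D,
YYYY年M月, M月D日, YYYY年, bare M月 (month-of-year), N{年|个月|周|天|日|小时}
with optional 前/后/来, and the named forms 今天/昨天/前天/明天/今年/去年/前年.
Absolute dates normalize to zero-padded ISO-8601; under-specified dates
keep their granularity (2008-03). Calendar-invalid days (2月30日) demote
to month granularity with a warning rather than failing. Bare N月 is read
as a month name, not a duration — durations of months are written 个月 in
this register — which is what lets 1月头痛，2月好转 yield two distinct
month nodes. Relative forms resolve against a reference date when one is
configured and otherwise stay symbolic; durations (20年) never resolve to
calendar points. Two-digit years are unsupported (they do not occur in
this date register).

## KV extraction

A KV entry is KEY + NUMBER (+ ×10^k) (+ UNIT), where KEY is an ASCII
identifier (WBC, Hb) or a Chinese measurement noun (体温, 脉搏), adjacency
without separators allowed (Hb102g/L). Everything is stored verbatim —
the magnitude text, the multiplier including its spacing, the unit even
when malformed (`/L/L` is flagged by `unit_warning`, not repaired) — so
that concatenating an entry's parts reproduces its source span exactly.
The context *t* comes from the colon introducer: location (在我院) and
verb (进行/行/复查…) prefixes are stripped, leaving the examination name
(血常规检查). Unit conversion, reference ranges and terminology mapping
are out of scope.

## TED assembly

Within a sentence, segments are processed left to right with a running
time node. A segment that is nothing but a date sets the node and emits
no triple. A colon-terminated examination introducer opens an event unit
that absorbs the following pure-lab segments into one merged KV set —
structurally those lab spans are separate segments (the delimiters say
so), but semantically they are one clause, and the merge reproduces the
single examination triple a clinician would read. Other segments emit a
triple when event-bearing (a clinical verb or negation, an outcome term,
a KV match, or a dated mention with residual content). Event/description
splitting is shallow by design: a trailing outcome term (无效/好转/…)
becomes the description; otherwise a leading verb from the small split
set (出现/诉/给予/行/进行/否认) becomes the event; otherwise the whole
clause is the event. The split set is intentionally narrower than the
set of verbs that mark a segment as event-bearing: 复查血常规 is an event
in its own right, not 复查 + 血常规.

Time inheritance is nearest-preceding within the paragraph (sentence
first, then earlier sentences), flagged `inherited`; it resets at
paragraph and section boundaries, since a new EMR section restarts the
narrative clock. Sentences with no time anywhere emit triples with a
null time rather than dropping them.

## Timeline and stages

Stage assignment is a keyword map, checked header first (既往史 → 1,
查体/入院诊断/辅助检查 → 2, 诊疗经过 → 3, 用药/医嘱/治疗 → 4,
出院/随访 → 5, 再次入院/复诊 → 6), then verb cues in the event
(leading 给予/予/行/服用 → 4; substring 治疗 → 4, 随访 → 5,
诊断/检查/化验 → 2), defaulting to the treatment process (3). Leading-verb
cues must open the event so that 行 does not fire inside 进行. Nodes sort
by earliest possible instant (a month at its first day, a year at
January 1), coarser dates first on ties; unresolved relative forms group
by surface form after all dated nodes, and untimed triples form a final
node. Durations ride on triples as attributes and never create nodes.
The recursion implied by a return visit containing a full admission of
its own is noted but not modelled across documents.

## Entropy model

All logs are base 2; the unit is bits. The character model is uniform
over N = 2500 characters (the conventional count of Chinese characters
in common use); N is configurable.

* **Raw (phase 0).** Each character is an independent uniform draw:
  log2 N ≈ 11.2877 bits per character, L·log2 N per note. Phase
  comparisons use the per-character value.
* **Phase I.** `H = (1/m) Σ_i Σ_j (−Σ p log2 p)/n_j`, where m is the
  sentence count, the inner sum runs over the k_i segments of sentence
  i, n_j is the segment's word (character) count, and −Σ p log2 p is
  the entropy of the segment's word distribution — log2 N under the
  uniform model. The division by n_j spreads the cost of identifying a
  segment across its characters: longer, more constrained clauses are
  cheaper per character, and H ≤ log2 N whenever sentences satisfy
  Σ_j 1/n_j ≤ 1 (true for clause lengths in this register). The inner
  expression is also defined for an explicit probability vector, which
  the oracle tests exercise.
* **Phase II.** A tagged segment's c terms get base mass
  `weight(pos)·(1/N)^{n_w}` (n_w = term length in characters; longer
  terms are exponentially rarer, and at equal length a noun outweighs a
  function word), renormalized within the segment to a proper
  distribution — the raw product is a weight, not a probability, and
  renormalization is what makes H_s = −Σ p(w) log2 p(w) a genuine
  entropy with H_s ≤ log2 c. Aggregation reuses the phase-I scheme with
  terms in place of characters: H = (1/m) Σ_i Σ_j H_s(j)/c_j.
* **Phase III.** Triples attach to time nodes. A resolved calendar
  anchor is structured data: the reader is given it rather than decoding
  it from text. We model this by letting each anchor absorb probability
  mass R/(R+1) from its attached segments' term distributions, where R
  is the number of resolved nodes in the timeline; by the chain rule the
  residual text entropy of an anchored segment is then its phase-II
  value scaled by 1/(1+R) (the anchor's own binary term is dropped
  because the anchor is given, not decoded). A node's entropy H_s(t) is
  the mean residual over its attached segments; unresolved nodes carry
  no discount. The timeline entropy is the convex combination
  `H_tl = Σ_t p_t H_s(t)` with p_t the node's share of attached triples
  (uniform weighting available via `p_t_mode: uniform`). Consequences,
  each property-tested: H_tl never exceeds the largest node entropy;
  redistributing fixed text over more resolved nodes strictly lowers
  H_tl; and on pipeline output H_tl ≤ H_phaseII ≤ H_phaseI ≤ log2 N.

The report flags any ordering violation (`monotone` / `violations`)
instead of hiding it.

## Synthetic data

The generator emulates the two archetypes of Chinese admission notes:
negated history enumerations (否认X、Y、Z史，W史N年) and dated event
chains (DATE出现SYMPTOM，给予DRUG±治疗OUTCOME，在我院进行EXAM检查：
KEY value unit, …), plus vital-sign clauses (体温38.5℃) and dated
follow-ups, optionally under section headers (既往史：…). Defaults: 100
notes of 2–6 sentences, dated sentences with probability 0.6 (15% of
dates relative), a five-analyte panel spanning the common blood-routine
keys with clinically plausible ranges, admission dates 2005–2015. These
sizes keep every corpus-level check comfortably fast while giving each
note enough temporal structure for the timeline stage to be exercised;
clause lengths are ≥ 6 characters by construction, which keeps the
phase-I per-character cost below log2 N structurally.

Gold annotations (time spans with exact offsets, KV signatures, triples
with stages) are derived from the templates at emission time, not by
running the pipeline, so recovery tests are meaningful. The vocabulary
is the packaged lexicon's closed world: 100% recovery is the expected
outcome and any miss is a regression. What passing these tests does
*not* show: robustness to typos, abbreviations, nested parentheticals,
free-order clauses, out-of-lexicon drugs/diseases, or OCR noise — real
EMR text has all of these, and the rule inventory would need extension
per corpus. `generate_growing_notes` grows one document cumulatively by
appending dated event-chain sentences (each text a prefix of the next),
the controlled setting used to study entropy as a function of document
size.

## Degenerate inputs and numerical choices

Empty notes yield empty hierarchies and all-zero entropy. Segments are
nonempty by invariant; tokenization of an empty string is a precondition
violation and raises. Probability vectors must sum to 1 within 1e-9;
entropy comparisons in tests use absolute tolerances of 1e-9 bits.
Sorting is stable everywhere; ties in node ordering break by document
order. JSON output uses fixed key order and 6-decimal floats for
byte-stable artifacts. Per-note seeds derive from the master seed as
`(seed·1000003 + i) mod 2^31`, so any note is reproducible in isolation.
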