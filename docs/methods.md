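# Methods

## Problem and model

Clinical letters cannot usually be shared: even after redaction they
are access-controlled, which blocks their use in teaching and model
training. This package synthesizes substitutes by *controlled
corruption and repair*: mask a chosen fraction of the tokens that carry
no protected meaning, then let a masked-language-model backend re-fill
the blanks. The output keeps the document skeleton (sections,
entities, dosages) and varies only the connective tissue, so its
fidelity/diversity trade-off is steered by one interpretable parameter,
the masking ratio.

The pipeline is a pure function of `(letter, config, seed, filler)`.
All randomness flows through seeded generators; per-chunk sub-seeds are
derived by hashing `(seed, note_id, chunk_index)`, so subsetting a
corpus never reshuffles another letter's mask plan.

## Data contracts

Letters arrive as CSV (`note_id`, multi-line quoted `text`);
annotations as CSV (`note_id`, `start`, `end`, `concept_id`). Offsets
are 0-based half-open character offsets — the convention is fixed here
and enforced by the invariant `text[start:end] == surface` at merge
time. Overlapping and nested entities are all retained; protection
uses their union. Lenient merging logs and skips annotations with
unknown ids or out-of-bounds spans, since real corpora are dirty;
strict mode raises.

## Chunking

Sentence segmentation is an adapter returning ordered spans; the
default is rule-based (breaks after `.?!` + whitespace and at line
breaks, since headers and medication lines are line-structured). A
"line" in the chunk limit means a sentence: that makes the unit
segmenter-defined and reproducible. Greedy packing appends sentences
while both limits hold, measuring tokens on the chunk's covering text
slice with the counting adapter (the filler's own tokenizer where
available — the budget exists to satisfy the model; default is the
word tokenizer). Sentences that alone exceed the budget are pre-split
at token boundaries, left to right. Entities crossing a chunk boundary
(possible only through such pre-splitting) stay with the chunk holding
their start, truncated and flagged: downstream masking needs
protection, not entity integrity.

The `max_lines` sweep reports mean tokens per chunk over an ascending
grid and selects the smallest grid point within ε of the maximum
(plateau start); ε defaults to 1 token. The plateau location is
corpus-specific and is reported, not asserted.

## Token features and eligibility

The word tokenizer is offset-faithful: `___`-runs are single tokens,
words keep internal apostrophes, numbers keep decimal points,
everything else is a one-character token.

- **Structure**: a physical line qualifies as a header when it ends
  with `:`, has ≤ 6 pre-colon tokens, and its alphabetic words are
  capitalized or all-caps (lowercase function words allowed, as in
  "History of Present Illness:"). Both thresholds are config
  overrides. A mid-line colon (`12:30`) never qualifies.
- **Private**: union of regex rules (email, phone with separators,
  UK/US postcodes, date-like patterns, bare 6+ digit runs) and an
  optional NER adapter contributing name/date/location spans. Adapter
  failure degrades to rules-only with a warning.
- **Clinical**: tokens under manual annotations (source
  `manual_annotation`) plus optional clinical-NER spans
  (`ner_adapter`); the manual layer never depends on the adapter.
- **Special patterns**: a config-extensible regex registry; defaults
  cover dose expressions and unit ratios (`40 mg/0.4 ml`), comparison
  doses (`> 200 mg`), and dotted abbreviations (`b.i.d.`).
- **POS**: any tagger emitting one fine tag per token; tags beginning
  `NN`/`VB` map to noun/verb, the rest to other. The built-in default
  is a deterministic lexicon-and-suffix tagger that is deliberately
  noun-heavy for unknown content words — adequate for driving masking
  pools, not a general-purpose tagger.
- Stopwords are a shipped editable list (standard 179-word English
  list); membership is case-insensitive.

Eligibility precedence: private → forced (only when de-identifying),
never eligible; then any of clinical/structure/special/punctuation/
placeholder/number → protected; else eligible. Placeholders are their
own feature class (not merely punctuation): masking must preserve
them, post-processing re-fills them.

## Mask selection

Per strategy component, the draw count is `k = ⌊r·|pool| + 0.5⌋`
(nearest integer, half up — fixed for testability). The draw takes the
first `k` elements of one seeded shuffle of the sorted pool, so draws
at growing `r` under a fixed seed are nested and the masked count is
provably non-decreasing in `r`. Hybrid strategies draw per component
and take the union; the overlap (Σk − |union|) is recorded so ratio
accounting stays exact. Forced private masks are excluded from the
eligible pool and from the eligible ratio, keeping strategy sweeps
comparable whether or not de-identification is active.

Rendering uses one mask symbol per word token even where a backend
tokenizer would split the word — word-level masking is the unit of the
whole design; per-piece masking is left to backend adapters. The
sentinel dialect assigns `<extra_id_k>` left-to-right, one per masked
word (contiguous masked words do not share a sentinel), and prepends
the fixed clinical fill-in-the-blanks prompt.

## Filling and validity

Fillers return exactly one top-1 prediction per slot, decoded
independently in a single left-to-right pass — no sampling and no
iterative refinement, so outputs are deterministic per backend. A
prediction is invalid iff empty/whitespace, devoid of alphanumeric
characters, or prefixed by the backend's declared sub-word continuation
marker (e.g. `##`). The invalid prediction rate is invalid/total over
a run and is an error when the run masked nothing.

Mock backends stand in for pretrained models: `IdentityFiller` (proves
losslessness), `ConstantFiller`, `LexiconFiller` (stable hash of seed,
left context and slot order over a fixed vocabulary — a deterministic
imitation of greedy decoding), and `NoisyFiller` (seeded injection of
invalid outputs). These are the test and no-download profile; real
adapters implement the same contract.

## Post-processing

Placeholder filling treats every maximal run of ≥ 3 underscores as one
slot, whatever the redacted content held — shorter runs are untouched.
Spelling correction is word-level and context-free by design; the
dictionary corrector inverts single adjacent transpositions (swapping
original characters, so displaced capitals are restored) and leaves
anything ambiguous or out-of-vocabulary alone. Protected spans are
never passed to the corrector.

## Evaluation

ROUGE-1/2/L are F-measures × 100 on lowercased alphanumeric word
tokens, no stemming; multiset n-gram overlap and LCS. Two texts whose
n-gram lists are both empty score 100 at that order; one-sided
emptiness scores 0. BERTScore is greedy-match precision/recall over
token-embedding cosines, unrescaled; the embedder is called once on the
concatenated token lists so per-pair embedders share a space. The
default one-hot embedder reduces it to exact-match overlap; a real
contextual embedder plugs in unchanged (reported values are
embedder-relative). METEOR implements the exact-match stage with the
standard fragmentation penalty `0.5·(chunks/m)³`; stemming/synonym
stages are adapter territory. Readability uses the standard FRE, FKGL
and SMOG formulas with a vowel-group syllable heuristic; SMOG is
computed even on letters below its 30-sentence design range and
flagged. Entropy is base-2 Shannon entropy of the word-frequency
distribution (the definition is fixed here). Subjectivity is a
lexicon adapter in [0, 1]; perplexity requires a causal-LM adapter and
is otherwise omitted.

Every similarity metric is reported in a pair: generation (synthetic
vs original) and the masked baseline (masked vs original). The
baseline is the floor; an identity filler attains the ceiling, which
gives the two ends of the scale an internal check.

## Downstream NER harness

Silver annotations come from a reference-tagger adapter, with overlaps
resolved longest-first; scoring is strict span+label micro-averaged
P/R/F1 (the harshest unambiguous matching mode; zero predictions score
0). Both corpora get the identical seeded 80/20 letter-level split
(never chunk-level, to prevent leakage), silver labels are always drawn
from the same source being evaluated, one tagger is trained per source,
and the delta is synthetic − original. The shipped adapters are a
gazetteer reference tagger and a memorizing trainer — minimal but
genuine learners that exercise the full harness deterministically.

## Fixture generator

The generator emulates the structure of annotated discharge summaries:
sampled colon-terminated section headers, templated sentences with
entity slots drawn from a concept-coded clinical term list, planned
`___` insertions (Poisson around the configured rate; the realized
count equals the plan), medication-dosage lines, occasional phone/email
contact sentences, and seeded adjacent-transposition misspellings
injected only outside gold spans and only where the corruption does not
collide with a real vocabulary word. Default rates (3–6 sections of
2–5 sentences, 0.6 entities per sentence, 2 placeholders per letter,
0.4 dosage-section rate, 0.3 contact-sentence rate) give letters of a
few hundred tokens — small enough to test at corpus scale, structured
enough to exercise every detector.

Gold labels are a sidecar never read by the pipeline. The generator
emits only in-grammar instances of each feature class, which is what
makes the recall-1.0 detector tests meaningful: they certify the
detectors on the grammar the generator covers, **not** on real clinical
text, whose headers, dose notations and PHI formats are messier. The
same caveat applies to all fixture-based results: they validate the
machinery (losslessness, protection, accounting, ordering), not
clinical realism.

## Problem sizes and numerical choices

Tests and the acceptance script run on generated corpora of 50–100
letters, 1,000 seeded mask plans for protection fuzzing, and ratio
grids of 6–11 points — sizes chosen so the full suite completes in
well under a minute per property while still exercising every
strategy × ratio × dialect combination. Ties in mask selection are
impossible by construction (the seeded shuffle is total); ties in the
corrector are broken lexicographically; degenerate inputs (empty
chunks, empty eligible pools, zero-sentence texts) either short-circuit
to well-defined values or raise typed errors, as documented per
function.

## Known limitations

- The default adapters are rule-based stand-ins: the POS tagger
  over-assigns nouns, the one-hot BERTScore embedder ignores synonymy,
  and the mock fillers model no language. Conclusions about *clinical
  quality* require real backends behind the same contracts.
- Spelling correction only inverts single adjacent transpositions;
  building a clinical spelling dictionary is out of scope.
- Entity linking against a terminology, model fine-tuning, hosted-LLM
  judging (only the prompt template ships) and inference-time
  benchmarking are out of scope.
- The masked-baseline tables' denominators are internal definitions
  (eligible vs actual ratio as defined above); they are self-consistent
  but not comparable against externally published tables computed on
  other corpora.
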