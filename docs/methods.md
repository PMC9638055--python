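# Methods

## Problem and pipeline

Clinical notes are dense with temporal expressions — explicit dates
("2/4/2013"), clock times ("9 a.m."), durations ("2 days"), frequencies
("b.i.d."), and, hardest of all, *relative* expressions whose calendar
position depends on another time or event ("2 weeks prior to admission",
"postoperative day three"). Before a relative phrase can be normalized it
must be typed: is "a week ago" a point in time (TimeML DATE) or a span
(DURATION)? That temporal type disambiguation (TTD) step is the core of
this package.

The pipeline is:

1. **Recognition** (`recognizer`) — rule families over raw text emit
   fine-grained entities: explicit dates/times, 2-place dates
   (`01/10`), quantity+unit periods, bare calendar intervals ("a week"),
   clinical abbreviations, frequencies, and temporal adverbs. Overlaps are
   resolved longest-match-first, ties by earliest start then rule priority
   (explicit date > explicit time > 2-place date > period/interval >
   frequency > adverb). Relative cue words ("ago", "prior", "past",
   "next") adjacent to a quantity+unit core are folded into the entity
   span so that lenient-overlap evaluation and the disambiguator's context
   window both see them.
2. **Conversion** (`timeml_converter`) — entities become TIMEX3
   annotations. Explicit dates normalize through `dateutil` (month-first
   slash order by default, configurable); 2-place dates take the admission
   year when the resulting date falls within ±6 months of admission,
   otherwise the candidate year nearest either reference date. Periods
   become ISO-8601 durations (`P2D`, `PT6H`); approximate quantity words
   resolve through a configurable table (couple→2, few→3, several→3,
   many→7 — the convention is a config default, not a constant) and carry
   an APPROX modifier. Without a disambiguation model the *naive rule*
   applies: every Period/Calendar-Interval is typed DURATION. With a model
   attached, the predicted type wins; relative DATE outputs keep an empty
   value because anchor-time and delta-value resolution are out of scope.
3. **Disambiguation** (`embedding_features` + `ttd_classifier`) — each
   ambiguous phrase is represented by a fixed-length vector built from
   per-subword, per-layer contextual embeddings and classified by a linear
   SVM (DATE = +1, DURATION = −1).

## Feature construction

An encoder provider returns per sentence a tensor (layers L, subwords S,
hidden H) plus a subword→token map. Rules, fixed across providers:

- a whitespace token is represented by its **last** subword; the last 4
  hidden layers are concatenated, ordered shallowest-of-the-four first
  (the order is a package convention; nothing downstream depends on it),
  giving 4·H per token (3,072 at H = 768);
- **Phrase-Only**: elementwise mean over the phrase's token vectors (4·H);
- **Phrase+Context**: mean of up to 3 tokens before ∥ phrase mean ∥ mean
  of up to 3 tokens after (12·H; 9,216 at H = 768). A window with 1–2
  available tokens uses just those; a window with zero tokens (phrase at a
  sentence edge, or phrase = whole sentence) is replaced by a duplicate of
  the phrase vector. Windows never cross sentence boundaries.

The shipped provider is a deterministic mock: each subword's layer vector
is a seeded hash of (subword surface, token position, layer), with tokens
longer than 6 characters split into two subwords. It preserves exactly the
properties the feature rules rely on — stable per-(surface, position)
vectors, subword/layer structure, configurable H and L — while being
reproducible and dependency-free. Any encoder exposing the same batch
contract (≥ 4 layers) can be swapped in; swapping changes values, never
shapes or rules. Alternative subword poolings (mean/sum) are deliberately
not implemented.

## Fine-tuning harness

`finetune_tasks` builds the two fine-tuning corpora: sentence-level binary
(temporal vs not, by gold-span overlap) and Seq2Seq token labeling under
BIO (9 labels) or Ttype (5 labels) schemes; token metrics exclude the
dominant O label and weight by gold support. Training is a contract —
`fit(dataset, base_provider, epochs, seed)` returns a derived provider and
a fitted task head — exercised at tiny scale with scikit-learn reference
heads (bag-of-words logistic regression; majority-label-per-surface
tagger). Sequential fine-tuning is the composition of two `fit` calls
chained through the derived provider. The harness makes no performance
claims; it exists so dataset construction, chaining, and metrics are
tested code.

## Corpus filters

- **DD filter**: keep DATE and DURATION annotations only (disambiguator
  training data — explicit phrases included so the model has more context
  to learn from).
- **RelIV filter**: additionally remove every explicit or incomplete
  expression — digit-bearing date forms, full or partial ("2/4/2013",
  "5/6"), clock times ("9 a.m."), month/weekday names, holiday names.
  The boundary rule: digits adjacent to a date separator mark a phrase
  explicit; digits attached to a unit word ("2 weeks prior") do not.
  The original subset was curated manually, so this rule-based
  reconstruction can differ on edge phrases; the rule, not the edge
  cases, is the contract.
- **Gold-overlap restriction**: for fair system comparison on the RelIV
  subset, system output is cut to annotations overlapping a RelIV gold
  span; all fragments of a split gold phrase are retained.

## Scoring

Matching is lenient (any character overlap), greedy one-to-one by maximal
overlap, ties by earliest system start. Span P/R/F1 count matched/added/
missed. Class-based metrics live on a 2×(2+na) confusion: gold DATE and
DURATION rows; an unmatched gold annotation falls in the `na` column and
counts as a false negative for its class; system-only annotations are
excluded. Per-class scores combine by gold-support weighted average.
Class accuracy would need true negatives, which the 2-class-plus-na
confusion does not define; it is implemented as the agreement rate over
matched pairs. Values compare by string equality after ISO
canonicalization (durations uppercased, `:00` seconds trimmed).

Error analysis buckets discrepancies into value / label / missed / added;
a value error is only counted when the label was correct. Shares of
value/label errors attributable to relative phrases are computed by
intersecting with RelIV membership. Difficult-file selection takes files
with min(P, R, value accuracy) ≤ 0.75 (threshold configurable).
Confidence intervals are percentile bootstrap over documents, seeded.

## Synthetic corpus

All tests run on generated sectioned discharge summaries (restricted
clinical corpora cannot ship). Default mixture follows the type
proportions of annotated discharge summaries: 44% explicit DATE, 24%
relative DATE, 19% DURATION, 3% TIME, 10% FREQUENCY, 10–16 phrases per
document plus header admission/discharge dates, with non-temporal filler
sentences interleaved (p = 0.4) so sentence-level datasets contain both
classes. Bookkeeping records each annotation's category and
explicit/relative status — the ground truth for filter and evaluation
tests. A perturbation routine fabricates system runs with known error
composition (drop/flip/value/add rates), giving evaluation tests an exact
oracle.

What the generator does *not* emulate: real lexical variety, section-
dependent anchor semantics, annotation noise, de-identification artifacts,
and discourse-level context. Tests passing here show the machinery is
correct under the stated conditions, not that real-corpus scores carry
over. In particular the disambiguation-signal test shows the SVM recovers
a linearly recoverable class signal from mock features (beating the
all-DURATION baseline); it does not claim real-text accuracy.

## Sizes and numerical choices

Test suites use 20–60 documents and mock hidden sizes 8–768 (the package's
own choice of problem sizes; everything scales by config). SVM defaults:
linear kernel, C = 1, override via config. Bootstrap default B = 1000,
95% percentile interval. Empty metric denominators return 0 by
convention. Non-contiguous phrases are rejected at featurization; the
recognizer only emits contiguous spans. All configuration is exposed as
CLI options and dataclass fields (lexicons are plain text files under the
package's `data/` directory, replaceable per run); there is no separate
config-file layer.
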