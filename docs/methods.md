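# Methods

This note documents the models and procedures implemented in `timetriage`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study corpora do and do not show.

## Problem setting

The task is binary document triage: given the full text of a research
article, decide whether it contains an evolutionary timetree (a phylogeny
with branch lengths in units of absolute time).  Such results are almost
always presented as figures, and the words that betray them ("divergence
time", "molecular clock", "timetree") also occur in articles that merely
*discuss* dating methodology.  The pipeline therefore combines corpus-level
phrase statistics with position-aware text selection around figure mentions.

## Text model

All stages share one normalization and one tokenizer, defined in
`timetriage.corpus`:

- **Normalization** lowercases, folds ligatures and diacritics to ASCII via
  NFKD with combining marks dropped (unmappable characters kept), folds
  CRLF/CR to LF and collapses horizontal whitespace runs to one space.
  Newlines are preserved verbatim: blank lines delimit paragraphs, and
  paragraph structure is what distinguishes figure captions from in-text
  mentions.  Normalization is idempotent and never changes the newline count.
- **Tokens** are maximal runs of `[a-z0-9]` on normalized text, so hyphenated
  words split.  Features are unigrams and bigrams of these tokens.
- **Document text** for matching and featurization is title + abstract +
  body, in that order (configurable).

## Phrase discovery

Unigram+bigram TFIDF features (`min_df` = 2 by default) are fit with an
L1-penalized logistic regression (liblinear coordinate descent, tolerance
1e-8).  The regularization strength is selected from the grid
{0.01, 0.1, 1, 10} by mean F1 over stratified 5-fold cross-validation, ties
to the first grid entry.  Grid values are calibrated to a reference corpus of
256 documents and the effective penalty scales as 1/n, which makes the
penalized objective — and hence the selected feature set — exactly invariant
under dataset duplication.  Features with strictly positive coefficients,
sorted by coefficient, form **PL**.

**Expansion.**  Word vectors are obtained by factorizing a positive-PMI
weighted co-occurrence matrix (symmetric window 5, minimum count 5) with a
truncated SVD to 100 dimensions — the closed-form counterpart of skip-gram
with negative sampling.  We chose the factorization route over stochastic
word2vec training because it is exactly reproducible on one CPU (ARPACK with
a fixed seed and a per-component sign convention) and trains in seconds on
desk-scale corpora.  For each PL **unigram** (bigrams are not expanded; the
embedding space is over words) the 10 nearest neighbors by cosine similarity
are pooled, deduplicated keeping each word's best similarity, stripped of
words already in PL, and filtered by corpus frequency (`min_count` = 5) to
drop rare combinations and misspellings, giving **WL**.  **FL** is the union
of PL and WL phrases.

**Queries.**  One simple query per FL phrase (the phrase quoted), plus
complex queries over consecutive groups of `complex_arity` phrases rendered
as `("p1") AND ("p2" OR "p3")`.  The boolean template is a fixed convention;
rendering is deterministic given FL order.

## Keyword filtering

A document is retained when its normalized title+abstract+body contains at
least one filter phrase at token boundaries; bigram phrases must match as
adjacent tokens.  No stemming by default: "divergence" does not match
"divergences".  Boundary matching is conservative and reproducible, and the
filter is recall-safe by design — the shipped default list (species,
evolution, molecular, phylogenetic, tree, clade, divergence, timetree) is
configuration, not ground truth.

## Excerpt extraction

The figure-token grammar matches, case-insensitively, `figure(s)` or the
abbreviation `fig(s)` followed by a dot or whitespace, an optional
supplementary marker before and an optional number after.  A mention that
starts a paragraph is a caption.  For a window of `w` characters (800 and
300 are the standard settings; minimum 50):

- in-text mentions yield `[max(0, offset - w/2), start + w)` — at the start
  of a document the window shifts rather than shrinks, at the end it clips;
- captions yield their whole paragraph regardless of `w`;
- overlapping or adjacent spans merge.

Offsets refer to the normalized body, so spans are platform-independent.
Documents with no mention keep an empty excerpt body and are listed in a
report rather than dropped — in a whole-text regime they are a known
false-negative source and must stay auditable.  A document's excerpts are
concatenated into one excerpt document before featurization (the default
`concat` strategy); a `max_score` per-excerpt alternative is provided.

## Representation

The TFIDF variant is pinned package-wide: raw term count × smoothed idf
`ln((1+N)/(1+df)) + 1`, rows L2-normalized, out-of-vocabulary tokens ignored
when a fitted vocabulary is re-applied (so train and test matrices align).
Embedding providers satisfy one contract — deterministic `embed(text)` of
fixed dimension, with truncation to the **first** `max_tokens` tokens for
bounded-input backends.  Two providers ship: trained document embeddings
(idf-weighted averages of the PPMI-SVD word vectors; `embed("")` is the zero
vector) and a feature-hashing mock (BLAKE2b-hashed token n-grams with hashed
signs, L2-normalized) that keeps the full pipeline testable with no
pretrained weights.  Contextual-transformer backends plug into the same
contract but are not shipped; their fine-tuning is out of scope.
*Representation enhancing* fits the vocabulary or embedding model on the
union of labeled and unlabeled corpora (ids must be disjoint) while
classification uses labeled rows only.

## Classification and evaluation

Nine families with default grids (tree depth {3,5,10,∞}, forest size
{100,300}, k ∈ {3,5,11}, C ∈ {0.1,1,10}, boosting sizes {50,100} /
{100,200}, bagging {10,50}); grids are configuration.  Selection is
stratified 5-fold cross-validation with a fixed shuffling seed, scored by F1
on the positive class; the winner is refit on all rows.  Degenerate inputs
(single class, minority class smaller than the fold count) are hard errors.
Predictions carry a positive-class probability; the positive label is
assigned at a threshold (default 0.5).  Evaluation reports exact confusion
counts; zero-denominator metrics are 0 with an explicit flag.  Percentages
from printed counts are rounded half-up (not banker's), matching how such
rates are conventionally reported.  Per-year precision tables contain only
years with at least one predicted positive, so the predicted-positive-
weighted mean of yearly precision reconstructs overall precision exactly.

## Synthetic study corpora

The generator (`timetriage.simulate`) emulates the structure the pipeline
assumes, with defaults chosen as the study conditions:

- 30% positive class balance; years uniform over 2000–2020.
- A shared Zipf-distributed background vocabulary (500 pseudo-words,
  exponent 1.1), so the per-class distributions of common words overlap.
- Signal phrases ("divergence time", "molecular clock", "timetree").  Every
  positive document carries at least one phrase within a couple of words of
  a figure mention; extra near-figure insertions scale with `signal_boost`
  (default 10).  Both classes additionally contain whole phrases away from
  figures (rate 0.25 per paragraph) — the methodology-mention error mode —
  and the constituent words of multiword phrases sprinkled into background
  sentences (rate 0.15 per sentence), so isolated words do not separate the
  classes; placement does.
- 1–3 figure mentions per document, 30% realized as standalone caption
  paragraphs; paragraphs separated by exactly one blank line.
- Single-character misspellings at rate 0.05 per token applied only outside
  400 characters of any figure mention, mirroring OCR noise that excerpt
  selection avoids.
- Per-document random substreams separate background text, boost-scaled
  insertions and misspelling noise, so `signal_boost` acts as a pure
  enrichment dial: at a fixed seed the background is identical across boost
  settings, and the per-class unigram distributions demonstrably converge as
  the boost approaches 1.  Output is bit-identical for a fixed config.

What passing tests on this data do show: the pipeline's mechanics (filter
recall safety, phrase recovery, the excerpt-over-whole-text advantage when
signal is figure-localized, determinism) behave as designed.  What they do
not show: performance on real articles, whose vocabulary is vastly larger,
whose signal placement is less regular, and whose labels are noisy; absolute
F1 values on synthetic corpora are not comparable to results on curated
data.

## Numerical and reproducibility choices

One seed drives every stochastic step (corpus generation, CV shuffling,
stochastic learners, embedding SVD).  Pipeline runs write a manifest with a
SHA-256 per artifact and a hash of the computation-defining config fields
(output directory and log level excluded); reruns with the same config and
seed are byte-identical, including the serialized model.  Benchmark sizes
(500-document filter corpora, 400-document recovery corpora, 600-document
excerpt-benefit corpora, 300-sample blob problems) were chosen so the whole
benchmark suite runs in minutes on a single CPU.

## Known limitations

- The figure-token grammar targets English conventions; "Plate", "Scheme"
  or non-English figure tokens are not matched.
- Count-based embeddings ignore word order beyond the context window and
  cannot disambiguate polysemy the way contextual models do; the provider
  contract exists precisely so stronger backends can be plugged in.
- The keyword filter is recall-safe only insofar as the phrase list covers
  the target literature; it is configuration the user owns.
- Excerpt windows are character-based, so a window may cut mid-word at its
  edges; features are token n-grams, which bounds the damage to one
  boundary token per span edge.
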