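# Methods

## Problem setting

Given free-text descriptions of genomics samples and of the datasets they
belong to, plus a tissue/cell-type ontology and a set of direct sample→term
annotations, the package learns per-term classifiers that map any piece of
text to a probability of describing that tissue or cell type. The package
covers the full pipeline — gold-standard construction, text preprocessing,
embedding pooling, model training and prediction, a dictionary-NER baseline,
grouped cross-validation, and prediction combination — together with a
synthetic corpus generator that makes every stage testable offline.

## Gold-standard construction

Annotations are propagated over the ontology restricted to a configurable
edge set (default `is_a` ∪ `part_of`, the convention of extended
anatomy+cell ontologies). For a term *t*:

* **positive** — the sample is annotated to *t* or to any descendant;
* **ignore** — otherwise, the sample is annotated to a strict ancestor of
  *t* (whether it belongs to *t* is ambiguous, so it is removed from both
  training and testing);
* **negative** — everything else.

Positivity takes precedence when a sample's annotations trigger both rules,
since a descendant annotation is unambiguous evidence. Dataset labels are a
strict majority vote over member samples (positive majority → positive,
ignore majority → ignore, otherwise negative; ties fall through to
negative). Only terms with positives from at least 3 datasets are trainable.
A sample listed in several datasets is assigned to one by a seeded
deterministic draw. Obsolete ontology terms are skipped with a warning;
edges to undeclared terms are dropped with a warning; a cycle in the
retained edges is a hard structural error.

Terms are optionally grouped into high-level anatomical systems by mapping
each modeled term to every system root among its ancestors; systems with 8
or fewer member models are dissolved (strict "> 8" threshold) and their
members labeled NA.

## Text preprocessing

Pipeline order: drop non-UTF-8-encodable characters → delete all Unicode
punctuation → collapse whitespace → split on spaces → drop tokens containing
digits, URL markers (`http`, `://`, `www`), or fewer than 3 characters →
lowercase → lemmatize. Deleting (rather than space-replacing) punctuation
means `RNA-Seq` becomes `rnaseq`; this is deliberate and documented
behavior. The Unicode punctuation category is used because sample metadata
contains typographic punctuation (em-dashes, curly quotes).

The lemmatizer is injected: the default is a no-op, and a conservative
idempotent English suffix stripper is provided (`ies→y`, trailing `s`
dropped only when ≥ 3 characters remain, so cleaned text survives
re-cleaning unchanged). A WordNet-style lemmatizer can be passed in by
callers that have one available; nothing in the core requires a model
download.

Sentences are segmented by a pinned rule: split after terminal `.` `!` `?`
followed by whitespace and an uppercase letter or digit (optionally behind
an opening quote/bracket). This keeps abbreviations like "e.g. liver"
intact and is deterministic; it will under-split stylistically unusual
text, which only affects how dataset descriptions are chunked before
max-pooling.

## Embeddings

IDF(t) = ln(N / n_t) over a corpus where each document contributes its set
of unique words. Natural log: the base rescales all weights jointly and
cancels in the weighted mean. An entity embedding is the weighted mean of
word vectors over the token multiset; a token with no stored weight gets the
(count-weighted) mean weight of the stored tokens in the same bag, so
misspellings still contribute through a character-robust backend. If no
token has a weight the pooling falls back to uniform with a warning.
Weighting schemes: `idf` (default), `tfidf` (IDF × within-class term
frequency, estimated from positive training samples only), `uniform`.

Backends satisfy a minimal contract — deterministic, defined for every
string, fixed dimensionality. The shipped `HashedBackend` derives a
unit-norm Gaussian vector from a keyed BLAKE2 hash of the word, giving
stable, platform-independent vectors at any dimensionality. Contextual
encoders (e.g. stacked character-level language models) satisfy the same
contract and can be plugged in; the pooling, training, and evaluation
contracts are independent of the backend choice.

Dataset descriptions are embedded one vector per sentence; empty sentences
are dropped, and a fully empty description yields an empty matrix that
downstream scoring reports as a missing value (never as probability 0).

## Models

One L1-regularized logistic regression per term (C = 1, liblinear solver,
fixed random state), trained on positive/negative entities after excluding
ignores; single-class training data is an explicit error naming the term.
The L1 solution path is not unique, so downstream claims are made on
rankings and on standardized-coefficient similarity, never on raw
coefficient values. No class weighting or probability recalibration is
applied. Trained models carry a fingerprint (backend id, dimension,
weighting scheme) to prevent accidentally mixing representations at
prediction time.

Dataset-level prediction is the maximum per-sentence probability. Any text
snippet can be scored by cleaning, embedding, and applying every model; an
empty token bag yields missing markers.

Model similarity (used to check that related terms learn related models) is
the cosine between coefficient vectors z-scored per feature across models.
The per-model alternative (z-scoring each vector) was considered and
rejected because it removes exactly the scale information that the L1
models share; with per-feature standardization the common background is
removed instead. A model whose raw coefficients are all zero is flagged and
given similarity 0 to every other model.

## Evaluation

Datasets — never samples — are partitioned into folds: positives are
shuffled (seeded) and dealt round-robin so every fold has one, negatives are
shuffled and dealt round-robin to balance sizes; ignored datasets are left
out. k follows data availability: 3 folds for 3 positive datasets, 4 for 4,
5 for 5+. Fold integrity (no dataset on both sides) is asserted on every
run.

auPRC is average precision with ties grouped at a common score threshold
(the PR curve is traced over unique score values). This tie rule was chosen
over rank-based tie-breaking by entity id because it makes a constant
scorer's auPRC equal the positive fraction — the prior, which is the
natural reference point and the denominator of the enrichment metric
log2(auPRC/prior). Per-fold auPRC is averaged over folds; folds with no
positive test sample are skipped with a warning. In the text-level CV
helper, IDF (and TF for the `tfidf` scheme) are re-estimated inside each
fold from training samples only, so held-out datasets never influence the
representation.

A Wilcoxon signed-rank comparison across terms is provided as a convenience
statistic (two-sided by default; scipy uses the exact distribution for
small tie-free samples).

## Combination schemes

F1-weighted method combination: each method's weight is its F1 at threshold
0.5; combined score = Σ F1_m·p_m / Σ F1_m. Binary annotators (dictionary
NER, external hit lists) enter with their 0/1 scores. When used inside
cross-validation, F1 weights must come from out-of-fold predictions on
training folds, never the evaluation fold — the CV helper enforces this by
construction since all scores it combines are produced by models that never
saw the evaluation fold. Sample+dataset combination adds the two
probabilities (a ranking score in [0, 2], not a probability) or takes their
maximum; a missing dataset score leaves the sample score unchanged.

## Synthetic corpus generator

The generator emulates the shape of curated repository metadata: a toy
ontology (a forest of `is_a`/`part_of` trees under system roots plus a
shared root), datasets of 16 samples each, ~30-token sample descriptions,
and ~8-sentence dataset descriptions built from member-sample tokens. Each
term owns a signature vocabulary (15 pseudo-words) and inherits a fraction
of each parent's effective vocabulary, so related terms share predictive
words the way related tissues share descriptive language. A positive
sample draws each token from its term's effective vocabulary with
probability `signal` and from a 300-word background vocabulary otherwise;
URL, numeric, and short-token noise is injected at 5% rates each. At
`signal = 0` the token distribution is identical across terms.

Two fixed study conditions are used throughout the tests and the
acceptance script:

* **Recovery conditions** (`inherit_fraction = 0.25`, the default): 10 leaf
  terms × 4 datasets × 16 samples at signal 0.8, hashed backend at
  dimension 128. Moderate inheritance keeps sibling terms separable, and
  the full pipeline recovers every term with mean CV auPRC ≥ 0.9; at
  signal 0 the CV auPRC equals the prior (the L1 penalty shrinks
  uninformative models to a constant scorer).
* **Similarity conditions** (`inherit_fraction = 0.5`): with half of each
  parent's vocabulary inherited, same-system term models have measurably
  higher coefficient cosine similarity than cross-system pairs. The two
  regimes are deliberately distinct: vocabulary sharing is precisely the
  dial that trades separability against relatedness, and each analysis
  probes one end of it.

What the generator does **not** emulate: real key-value metadata structure,
field names, abbreviations and misspellings with lexical structure,
inter-annotator noise in the gold standard, or the heavy-tailed dataset
sizes of real repositories. Passing tests therefore demonstrate the
correctness of the pipeline's contracts and its ability to recover a known
signal, not the absolute accuracy achievable on real repository metadata
with pretrained contextual embeddings.

## Numerical choices and degenerate inputs

* Natural log in IDF; zero weight for words in every document is valid
  input to the pooling (their mass drops out unless all weights are zero,
  which triggers the uniform fallback).
* Empty token bags embed to the zero vector; scoring layers report missing
  values for them rather than probabilities.
* Probabilities are computed through the logistic link from stored
  coefficients, so serialized models reproduce predictions exactly.
* Fold assignment, corpus generation, backend hashing, and sample→dataset
  assignment are all seeded; identical configuration + seed gives
  byte-identical outputs.
* Problem sizes in the tests and acceptance script (640-sample corpora,
  dimension 128, 10–20 replicate seeds) were chosen so the full suite runs
  in well under a minute of compute per property while keeping Monte-Carlo
  noise far from the asserted margins.

## Known limitations

* The hashed backend carries no semantics: two related words get unrelated
  vectors. That is sufficient (and intended) for testing the pipeline's
  contracts, but real deployments should inject a pretrained
  character-aware encoder.
* Exact-match NER is scored without hierarchy expansion (a "cerebral
  cortex" hit does not set "brain"); whether matched terms should be
  propagated up the ontology before scoring is left open, and propagation
  is applied at labeling instead.
* The suffix-stripping lemmatizer is intentionally minimal; irregular
  plurals and derivational morphology pass through unchanged.
* `part_of` edges participate in descendant-based positives by default;
  restrict the edge set at parsing time if subclass-only propagation is
  wanted.
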