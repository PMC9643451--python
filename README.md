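# textannot

Ontology-aware tissue and cell-type annotation of genomics samples from
their unstructured, free-text metadata.

Public repositories hold millions of human -omics samples whose descriptions
are written in inconsistent natural language, which makes finding "all the
liver samples" far harder than it should be. `textannot` treats each sample
description as a bag of words, turns it into a numerical embedding, and
trains one supervised classifier per anatomy/cell ontology term to predict
whether a sample comes from that tissue or cell type. It is aimed at
bioinformaticians and data curators who want structured, ontology-grounded
annotations over large metadata collections — and at anyone who needs a
fully testable, offline reference implementation of this kind of pipeline.

## Method

**Labels.** Direct sample→term annotations are propagated over the ontology
DAG (`is_a` ∪ `part_of` by default) under the true-path rule: for a term
*t*, a sample is **positive** if annotated to *t* or any descendant of *t*,
**ignored** (excluded from training and testing) if annotated only to a
strict ancestor of *t*, and **negative** otherwise. A dataset is positive
for *t* if a strict majority of its samples are; models are trained only for
terms with positives from ≥ 3 datasets.

**Embeddings.** Descriptions are cleaned (punctuation deleted, tokens with
digits/URL markers or fewer than 3 characters removed, lowercased,
lemmatized) into token multisets. A sample embedding is the element-wise
weighted mean of its word vectors,

    v = Σ_t w(t) · e(t) / Σ_t w(t),      w(t) = IDF(t) = ln(N / n_t),

where *N* is the corpus size and *n_t* the number of documents containing
*t*; a word with no stored IDF receives the mean weight of the weighted
words in the same description. Word vectors come from any deterministic
`EmbeddingBackend` (character-level contextual encoders plug in here; the
package ships a seeded hashed backend so everything runs offline).
Multi-sentence dataset descriptions become one vector per sentence, scored
by the maximum per-sentence probability.

**Models.** One-vs-rest L1-regularized logistic regression per term
(C = 1, liblinear), trained on positive/negative samples only. Any snippet
of text — an ontology term's name + definition, a process description — can
be scored by the same models.

**Evaluation.** Dataset-stratified k-fold cross-validation (samples of a
dataset are never split across folds; k = 3, 4, or 5 by positive-dataset
count), scored by auPRC (average precision) and log2(auPRC/prior). IDF and
TF weights are re-estimated inside each fold from training samples only.

**Baselines and combination.** A dictionary NER baseline scores a term 1/0
by exact word-boundary matching of its name and synonyms; external binary
annotators are consumed from (entity, term) hit lists. Predictions from
several methods are combined by an F1-weighted average; sample and parent-
dataset predictions are combined additively into a ranking score.

## Worked example

Generate a synthetic corpus (10 leaf terms under 2 anatomical systems,
4 datasets per term, 16 samples per dataset, 30-token descriptions with a
0.8 tissue signal), build labels, and run the dataset-stratified CV:

```
$ textannot simulate --n-terms 10 --seed 0 --outdir demo
wrote 640 samples, 40 datasets to demo

$ textannot build-labels --ontology demo/ontology.obo \
    --annotations demo/annotations.tsv --outdir demo/labels
10 trainable terms of 10 annotated

$ textannot evaluate --ontology demo/ontology.obo --samples demo/samples.tsv \
    --datasets demo/datasets.tsv --annotations demo/annotations.tsv \
    --outdir demo/eval --seed 0
       term  n_pos  k  mean_auprc  prior  log2_enrichment anatomical_system
TOY:0000004     64  4    1.000000    0.1         3.321928                NA
TOY:0000006     64  4    0.993887    0.1         3.313082                NA
...
```

Each row is one term's model: `mean_auprc` is the average precision on
held-out datasets averaged over folds (here using the additive
sample+dataset combination), `prior` is the positive fraction (0.1 — a
random ranking's expected auPRC), and `log2_enrichment` says the model
ranks positives ~10× better than chance (log2(1.0/0.1) ≈ 3.32).

Train models and score an arbitrary snippet:

```
$ textannot embed --samples demo/samples.tsv --dim 128 --out demo/emb.tsv
$ textannot train --embeddings demo/emb.tsv \
    --sample-labels demo/labels/sample_labels.tsv --outdir demo/models
$ textannot predict --models demo/models --idf demo/emb.tsv.idf.tsv \
    --dim 128 --text "doloma vosebe furoli gipimi tasuka ..."
TOY:0000004	0.3465
TOY:0000010	0.0783
TOY:0000011	0.0482
```

The top-scoring term (probability 0.35 vs ≤ 0.08 for all others) is the
sample's true annotation.

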