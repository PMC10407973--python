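# Methods

## Pipeline

The system builds an augmented training set for drug–protein relation
extraction and trains in phases:

1. **Preprocessing.** Each document's `full_text` is the title and
   abstract joined by a single tab; offsets are 0-based, end-exclusive,
   and every entity span is validated to slice `full_text` to exactly its
   surface string. A rule-based splitter (split at the title/abstract tab
   and after sentence-final punctuation followed by whitespace and an
   uppercase/digit/bracket start) produces sentence windows; external
   splitters plug in through the same text → offset-pairs contract.
   Mentions fully inside a window attach to it; mentions crossing a window
   boundary are dropped and counted. Candidates are the cartesian product
   of chemical × gene mentions within one sentence — relations are
   within-sentence by task definition.

2. **Marking.** One input sequence per candidate pair: only the pair's two
   mentions are marked (co-occurring mentions stay raw text), matching a
   classifier that scores a single pair per sequence. Four variants are
   implemented — no marking, masking, typed wrapping, and typed start/end
   wrapping (`CHEM-S … CHEM-E` / `GENE-S … GENE-E`, the default). Typed
   start/end marking is exactly invertible by deleting the four marker
   tokens and their padding spaces. Nested/overlapping spans are marked
   innermost-first; for identical spans the chemical markers go outside
   (deterministic, invertible; no convention is forced by the task).

3. **KB refinement.** A CTD-style chemical–gene table is indexed by
   case-normalized (chemical id, gene id) pair; duplicate rows merge and
   supporting PMIDs union. Agreement is symmetric on pair presence only:
   positive pseudo-labels survive iff the pair is listed, NONE
   pseudo-labels survive iff it is not; everything else is dropped and
   refinement never rewrites a label. The symmetric rule for NONE follows
   from treating the KB as the arbiter of pair relatedness in both
   directions; it also filters pseudo-negatives that distant supervision
   would call positive. No type mapping is attempted because KB action
   vocabularies and corpus label schemas differ. Mention linking uses the
   entity's normalized id when present, else its case-folded,
   whitespace-collapsed surface form; unlinked pairs count as absent and
   are reported.

4. **Two-phase training.** Phase 1 fits a fresh classifier on the
   augmented set; its parameters are exported and imported (the transfer
   step — with zero fine-tune steps the transferred model reproduces
   phase-1 predictions exactly); phase 2 continues training on the gold
   data with the same configuration as the labelled-only baseline. An
   empty augmented set falls back to single-phase training with a warning.

## Reference classifier

A multinomial logistic regression over hashed sparse features of the
marked sequence, trained by mini-batch SGD on softmax cross-entropy:

* **Features.** Word unigrams/bigrams plus character 3–5-grams within
  tokens (lower-cased, boundary-padded), all hashed into 2^18 buckets
  (murmurhash). Marker tokens are asserted to tokenize as single units and
  are excluded from character decomposition, so they behave as atomic
  vocabulary items whose hashed weights are trainable parameters — the
  desk-scale analogue of registered special-token embeddings. The
  character n-grams approximate the subword vocabularies of transformer
  backbones and let the model generalize across morphological variants
  ("antagonist"/"antagonized"); without them, pseudo-labels on template
  variants unseen in the labelled split are systematically mistyped, which
  is exactly the noise KB pair-presence checking cannot catch.
* **Schedule.** Learning rate rises linearly from 0 to the peak over the
  first `warm_rate` (default 0.05) fraction of `max_steps`, then decays
  linearly to 0 at the final step.
* **Defaults.** peak_lr 0.5, batch 32, 400 steps, L2 1e-6 (applied lazily
  to features active in the batch), zero-initialized weights, seeded batch
  order: training is exactly reproducible from (data order, config, seed).
  The peak rate is large by transformer standards because the features are
  sparse binary counts and the model is linear.
* **Inference.** Scores are softmax probabilities over the 14 labels
  (13 types + NONE as a predicted class, matching the confusion-matrix
  framing); argmax ties resolve to the lower canonical label index.
  Entities are not anonymized by default (non-anonymized input performs
  best in ablations).

## Evaluation

Tuple-match scoring: TP iff the predicted (pmid, arg1, arg2, type) tuple
exists in gold; a wrong-type prediction on a gold pair is one FP (its
type) plus one FN (the gold type); NONE predictions generate no FP. Micro
scores sum counts over the 13 positive types. Zero denominators report 0,
the common challenge-scorer convention. Confusion counts are per pair key
over (gold type or NONE) × (predicted type or NONE), with an option to
omit the NONE prediction column for rendering. Report differences are
b − a per cell in percentage points.

## Synthetic corpora

The generator emulates the corpus triplet (abstracts, entities,
relations), a CTD-style KB, and a ground-truth manifest:

* Sentences come from per-type trigger templates (3 per type), built to be
  unambiguous so a desk-scale linear model can learn them; neutral
  co-occurrence templates supply NONE pairs with probability
  `p_negative_cooccurrence` (default 0.3), and with probability
  `p_distractor` (0.25) a sentence gains a second, unrelated gene mention —
  the case where entity marking is informative and unmarked input is
  provably ambiguous.
* The label distribution defaults to the DrugProt training-set
  proportions, preserving the heavy skew including the three <0.3% types,
  which remain effectively unlearnable at these corpus sizes — matching
  the rare-type behaviour seen at full scale.
* The KB lists each distinct planted positive pair with probability
  `kb_coverage` (0.9) with its supporting document ids, plus `kb_noise`
  (50) pairs that never co-occur in the text, citing documents outside the
  corpus.
* Defaults chosen as the standard study conditions: 300 documents of 3–8
  sentences, 120-surface chemical and gene lexicons with MeSH-/NCBI-style
  normalized ids. Generation is byte-deterministic given the config.

What the fixtures do **not** emulate: real biomedical syntax, name
ambiguity and linking errors, cross-sentence or n-ary relations, and
KB/corpus vocabulary mismatch beyond pair-level noise. Passing results
demonstrate pipeline correctness and the *direction* of the
weak-supervision effect, not real-corpus performance levels.

## Recovery experiment

`training.run_recovery` splits a 300-document corpus at document level
into a labelled set (n/15 = 20 documents — the annotation-scarce regime
the method targets), a weak pool ten times larger, and the remaining 80
documents held out. The baseline trains on the labelled set alone; the
system weak-labels the pool with the baseline model, refines by KB
agreement, pretrains 1500 steps on the kept examples, and fine-tunes with
the baseline's own configuration. Both are scored on the same held-out
gold. With a perfect classifier, the fraction of distinct planted pairs
surviving refinement is a binomial estimate of `kb_coverage`.

## Resplitting and checkpoints

The merged train+dev resplit is document-level (sentences from one
abstract never straddle a train/dev boundary): pmids are shuffled by seed
into k = 10 disjoint partitions; pair i uses partition i as dev and the
rest as train. Checkpoint selection takes the highest dev micro-F1,
earliest step on ties; the default cadence is 2000 steps.

## Known limitations

* KB agreement checks pair presence only, so wrong-type positives on
  KB-listed pairs pass the filter; this is the dominant pseudo-label noise
  and is mitigated, not removed, by subword features.
* The three rarest relation types are below the learnable threshold at
  desk scale; per-type scores for them are 0 in most runs.
* The rule-based splitter has no abbreviation model; entities crossing its
  boundaries are dropped (counted, and rare on the fixtures).
* The reference classifier is linear; it validates the pipeline contracts
  and directional claims, while real-scale accuracy requires a transformer
  backbone through the adapter contract.
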