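# Methods

## Task and representation

A triplet relationship (gene, chemical, disease) is evidenced by a pair of
sentences from a single abstract.  Under the default configuration the
*relation sentence* carries a gene and a chemical mention and the *context
sentence* carries a disease mention; when all three mentions share one
sentence the pair is that sentence duplicated.  Candidate pairs are
enumerated exhaustively: every (gene, chemical) mention pair co-occurring in
a sentence is crossed with every disease mention within a configurable
sentence distance (unlimited within the abstract by default), deduplicated
on the (relation sentence, gene mention, chemical mention, disease mention)
tuple.  The context sentence may precede or follow the relation sentence.
Two symmetric configurations — (chemical, disease)+gene and (gene,
disease)+chemical — are implemented with the relation anchor taken from the
first-named entity of the configuration.

Entity annotations are consumed, not produced: input is PubTator-format
text (title/abstract lines plus tab-separated mention lines with character
offsets, entity type and normalized ID).  Offsets are 0-based half-open into
`title + " " + abstract`.  Annotation types outside {gene, chemical,
disease} are dropped; annotation lines whose surface string does not match
the offset slice are skipped and counted; mentions with ID `-` are kept but
marked unnormalized.  Sentence segmentation is a deterministic rule-based
splitter (boundary at `[.!?]` + space + non-lowercase, with an abbreviation
and single-initial veto list); a mention crossing a proposed boundary causes
the flanking spans to be merged, so every mention lies in exactly one
sentence.  How the original system handled such mentions is unknown; merging
is this package's choice, as is the splitter itself (I/O deliberately needs
no parsing model).

## Features and aligned encoding

Each token is the concatenation of a word vector (`d_word = 200`) and an
entity-type vector for its BIO tag (`d_ent = 20`; 7 tags), 220 values per
token.  Word vectors can be loaded from a plain-text embedding file; absent
a pretrained file, rows are drawn from uniform(−0.05, 0.05) with a seeded
generator, with one shared trainable unknown-word row and an all-zero
padding row.  Tag vectors are randomly initialized the same way.

**Both tables are trainable by default.**  Freezing word vectors only makes
sense when they carry pretrained distributional information; with random
initialization the lexical signal must reach the model through the embedding
rows, and freezing them measurably cripples learning (train F 0.88 frozen
vs 1.00 trainable at the default hyperparameters on the synthetic task).
`freeze_word_vectors=True` restores the frozen behavior for the pretrained
case.  The padding row is exempt from updates and stays exactly zero.

A pair is encoded as a 2-D array whose columns are time steps.  Parallel
strategies stack the sentences as two row blocks (440 rows): each sentence
is left-padded so the two anchor tokens (first token of the gene mention and
of the disease mention, by default) share a column, then right-padded to a
common length.  Which side the original system padded is unstated; the
left/right scheme here is one consistent choice, with masks marking real
tokens and recurrent layers carrying state through masked columns unchanged.
The aligned length is computed per batch, not corpus-wide.  A cap of 128
tokens per sentence truncates pathological sentences from the right but
never removes an anchor or mention token.  The sequential strategy appends
the context sentence after the relation sentence with one padding column
between (220 rows).

## Classifier

The default architecture is a bidirectional LSTM: 100 hidden units per
direction read the 440-row column sequence; forward and backward states are
concatenated per step (200 values), passed through a 1000-unit
fully-connected ReLU layer per step, max-pooled over time, and projected to
a 2-way softmax.  The sequence-to-decision reduction is not specified by the
task description; max-over-time is the default here, with mean-over-time
and final-state behind a config switch.  Comparators share the identical
contract: unidirectional LSTM/GRU, bi-GRU, and a CNN (one convolution layer,
window 3 over columns, `hidden_units` filters, ReLU, max-over-time, then the
same fully-connected head).

Training minimizes 2-class cross-entropy (mean over the mini-batch) by plain
SGD — a learning rate of 0.80 is only plausible without adaptive scaling —
with seeded shuffling, mini-batches of 200, and global-norm gradient
clipping at 5.0 (the one stabilizer added; at this learning rate the loss
otherwise spikes during the transition out of the plateau).  Defaults:
hidden 100, learning rate 0.80, fully-connected 1000, batch 200, threshold
0.5, 30 epochs, no dropout (a dropout hook exists), no class weighting.  On
the synthetic task the loss plateaus near ln 2 for ~10 epochs and then
drops sharply; 30 epochs is comfortably past convergence for corpora of
500–1500 pairs.  All layers (LSTM/GRU/conv/dense and their
backpropagation) are implemented in numpy in `tripmine.nn`, verified
against numerical differentiation to ~1e-9 in float64; training runs in
float32.  Everything is deterministic given the config seed: parameter
initialization, shuffling and fold assignment.

Evaluation reports precision, recall and F = 2PR/(P+R) from confusion
counts at the 0.5 threshold.  Cross-validation partitions with seeded
stratified folds (per-class sizes within 1; scikit-learn's StratifiedKFold
behind the package surface); each fold trains a fresh model from a fresh
copy of the embedding table so trainable embeddings cannot leak across
folds.  The imbalance protocol subsamples (n_pos, n_neg) pools with a
seeded generator and cross-validates each subsample; the headline comparison
is 500+500 vs 500+1000 with k = 2 folds (k chosen for runtime at these pool
sizes; the fold count is a protocol parameter, not part of the model).

## Post-processing rules

Five deterministic rules remove likely false positives from
predicted-positive pairs; all enabled rules are evaluated on every pair (no
short-circuit), a pair is kept iff none fired, and the kept set is
independent of rule order.

* **i — dictionary membership.**  Fires unless every one of the three
  mention surfaces, case-folded, appears in the synonym set of its
  normalized ID.  Unnormalized mentions (`-`) always fire; the rule's
  purpose is dictionary validation.
* **ii — type conflict.**  Fires when any mention span in either sentence
  overlaps a mention span of a different entity type.
* **iii — study-purpose vocabulary.**  Fires when any token of either
  sentence, lower-cased with cheap plural stripping, is a hyponym of
  "study".  The hyponym list is a frozen curated snapshot shipped as a
  resource file so behavior cannot drift with lexicon versions; it
  deliberately excludes "analysis" (not a hyponym of "study", and common in
  true-positive wording such as "Western blot analysis").
* **iv — negation keywords.**  Whole-token match against a configurable
  list ("not", "never", ...; contracted negations via an `n't` suffix
  check).  "note" does not fire.
* **v — gene–chemical coordination.**  Fires when the gene and chemical
  mentions are linked by a conjunction in the relation sentence.  The
  detector is an injected interface; the bundled default is a deterministic
  surface pattern (only commas/"and"/"or" between the two mentions), which
  is what a dependency parse would label as a conjunct link in these cases
  and keeps the rule testable without a parsing model.

Rules iii and iv are applied to *both* sentences of the pair (the scope is
ambiguous in the task description; the both-sentence reading is this
package's documented choice).

## Search

Positive evidence pairs are stored with their normalized ID triple, score
and sentence texts; one posting map per entity type sends an ID to the pair
identifiers mentioning it.  Queries are conjunctive across the three fields
and disjunctive within a field; empty fields are unconstrained.  Name terms
resolve through the synonym dictionaries by case-insensitive exact match (a
synonym shared by several IDs expands to all of them); bare IDs present in
the index are honored directly.  Results are sorted by score descending
with deterministic (doc_id, sentence index) tie-breaks; a grouping option
collapses results to unique triplets with best score and evidence count.
The index is persisted as line-oriented text files and reloadable; no
external search-engine dependency.

## Synthetic study conditions

The generator emulates the gold-corpus construction: each document plants
one triplet, single-sentence with probability 0.5 (mirroring the
half-and-half composition of the gold data), positive with probability 0.5.
Negatives draw evenly from four patterns matching the false-positive
taxonomy the filters target: co-occurrence-only, negated, study-purpose and
unrelated-disease.  Default vocabulary: 40 genes, 40 chemicals, 25 diseases
(distinct G#/C#/D# namespaces), 2 synonyms per entity, filler words from a
fixed shipped list.  Mention surfaces are drawn from the generated synonym
dictionaries, so dictionaries are complete by construction and rule i fires
only on corrupted input.  `corrupt_annotations` injects seeded NER-style
errors — same-length off-dictionary surface rewrites (rule-i targets) and
duplicate spans with conflicting types (rule-ii targets) — with a manifest.

Positives and negatives are lexically separable by template cues by default
(a `hardness` knob adds cue-word overlap); a bag-of-words logistic baseline
certifies held-out F ≥ 0.9 before any neural result is interpreted.
Passing on this corpus therefore demonstrates *pattern recovery* — that the
encoding, model, training loop and protocols work end-to-end — not
performance on real biomedical language, which is harder in every way
(ambiguous entities, long sentences, discourse-level negation, NER noise).
Reported problem sizes: pattern recovery uses 500+500 pairs with an 80/20
split; the imbalance comparison uses 500+500 vs 500+1000 with 2-fold CV
(5 seeds in the test suite, 3 in the acceptance script); contract checks
use 1000 pairs/queries.

## Known limitations

* Absolute F on the original gold corpus is not reproducible here: that
  corpus is unreleased, and the synthetic task is intentionally easier.
* Word vectors are not distributionally pretrained; transfer claims about
  embedding quality are out of scope.
* Rule v's bundled detector covers simple coordination only; a real
  dependency parser can be injected for nested coordination.
* Negation is keyword-based (as in the filter design), not scope-aware.
* The search index performs exact (case-insensitive) synonym matching; no
  fuzzy matching or ontology expansion.
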