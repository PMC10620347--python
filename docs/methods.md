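# Methods

This note documents the models and procedures implemented in `carestrat`,
the calibration of the synthetic corpus generator, and the design choices
made where the study description left the design open.

## Labels and tasks

Records carry one of five labels: `ENV` (environment/context, the extrinsic
construct), `SELF`, `PREF`, `COMP` (the intrinsic constructs) and `NONSTRAT`
(entries that do not describe a strategy). Four tasks are derived from them:

1. strategy vs non-strategy over all records;
2. extrinsic vs intrinsic over strategy records;
3. `SELF`/`PREF`/`COMP` over intrinsic records;
4. flat five-way classification.

Cascaded inference composes tasks 1–3: a stage-1 `NONSTRAT` prediction stops
the cascade, a stage-2 `EXTRINSIC` prediction stops with `ENV`, otherwise
stage 3 decides among the intrinsic classes. With oracle stage models the
cascade is the identity on gold labels, which is asserted in the tests.

## Synthetic corpus generator

The real corpus is not public; the generator is calibrated **only** to its
published aggregates, which are also the generator defaults:

| parameter | default | source |
|---|---|---|
| class counts | 975/307/84/104/106 | published counts |
| mean lengths (tokens) | 7.20/6.60/7.64/5.85/5.21 | published per-class means |
| shared vocabulary | 2,000 types | chosen so realized vocabulary ≈ published 2,337 |
| keywords per class | 40 | calibration choice |
| discriminability | 0.8 | calibration choice (learnable, not trivial) |
| noise rates | 0.05 each | calibration choice |
| refusal probability | 0.5 | class described as mixing one-word refusals with diverse sentences |
| seed | 42 | every randomized operation takes an explicit seed |

Record lengths follow a shifted Poisson `1 + Poisson(mean − 1)` — positive,
integer-valued and mean-matched; the published statistics contain no length
variance to calibrate against. Each content token comes from the record's
class keyword pool with probability `discriminability`, else from a shared
class-neutral vocabulary (common English words padded with deterministic
pronounceable pseudo-words to the configured size; the shared vocabulary is
a fixed property of the synthetic language, independent of the corpus seed).
Surface noise is injected per token: misspellings (one character edit),
personal names, digit strings, attached punctuation and stopword fillers,
each at its configured rate; these replace or decorate tokens so the token
count — and hence the calibrated mean length — is unchanged. Non-strategy
records are a fixed refusal template ("none", "no strategies needed", …)
with probability `refusal_prob`, else a sampled sentence whose length mean is
adjusted so the class mean still matches the published 5.21.

At the default settings the realized corpus lands at 10,954 tokens and 2,401
vocabulary types against the published 10,804 and 2,337, with per-class mean
lengths within 0.3 tokens (`analysis/01_generate_corpus.py` prints the
comparison).

What the generator does **not** emulate: real syntax and discourse (records
are bags of templated tokens with an opener), semantic overlap between
classes beyond shared vocabulary, annotator noise in the labels, and setting
covariates (home/school/community). Consequently, passing parameter-recovery
tests shows that the pipeline recovers a lexical class signal under realistic
size/imbalance/noise conditions — it does not predict performance on real
caregiver text, where the published accuracies (94.92/85.71/83.84/78.10) are
explicitly not reproducible.

## Concept lexicon fixture

The study's manual UMLS mapping produced 71 concepts (38 environment, 15
sense of self, 12 preferences, 6 activity competence), 49 of which mapped to
existing UMLS concepts (22 unmapped, split 12/6/3/1 per class). The mapping
table itself is not distributed, so
`data/synthetic_concept_lexicon.tsv` is a constructed stand-in with exactly
that shape: concept names templated over the generator's class keyword
pools, one to three trigger keywords each, the mapped flag, and a
source-vocabulary tag for mapped concepts. Trigger keywords deliberately
overlap the keyword pools so concept features are informative on synthetic
corpora. Concept assignment is automated trigger matching over preprocessed
tokens; the study's assignment was manual, and this fidelity gap is inherent
to any reimplementation without the original mapping.

## Preprocessing

Order: (1) lowercase, (2) spelling correction, (3) name/number placeholder
replacement, (4) punctuation removal, (5) stopword removal, then
lemmatization. Entity replacement precedes punctuation removal so the
bracketed placeholders survive; placeholders are exempt from correction,
stopword removal and lemmatization, making the pipeline idempotent on its
own output (tested).

* **Spelling correction**: out-of-dictionary alphabetic tokens are replaced
  by the nearest dictionary word within edit distance 2 (ties: smaller
  distance, then higher training-corpus frequency, then lexicographic). The
  dictionary is the bundled ~580-word list plus training-corpus words seen
  at least twice — one-off misspellings must not become valid spellings —
  and is always built from the training split only. Gazetteer names are
  never "corrected" so the later entity step can see them.
* **Stopwords**: a fixed 127-word English list shipped as a data file, for
  byte-stable results; "none" is deliberately not a stopword so refusal
  records survive.
* **Lemmatization**: irregular-form exception table plus suffix rules for
  plural/-ing/-ed with e-restoration and consonant undoubling; a suffix is
  stripped only when the resulting stem is dictionary-confirmed, so the
  rules never invent words.
* Records normalized to emptiness are retained with an `empty` flag so
  counts reconcile downstream.
* The name recognizer is a gazetteer over the generator's name inventory
  plus a digit rule; the study used a statistical recognizer with manual
  checking, which cannot be automated faithfully.

## Representations and features

* **TF-IDF**: vocabulary = the ≤5,000 most frequent training words
  (interpreted as a frequency-ranked cap; ties lexicographic);
  `idf = ln((1+N)/(1+df)) + 1`; vectors L2-normalized; out-of-vocabulary
  tokens ignored. The dialect is recorded in the model and cross-checked
  against an independent implementation in the tests.
* **Paragraph vectors**: own distributed-memory implementation with negative
  sampling (5 negatives, unigram^0.75 noise), window 5, linear learning-rate
  decay 0.025 → 1e-4, single-threaded and fully seeded; inference freezes
  word and output weights and trains only the new document vector, so
  inferred vectors are deterministic. Defaults follow the study setup:
  dimension 100, minimum count 1, 30 epochs.
* **PMI likely word sets**: `PMI(w,c) = ln p(w,c)/(p(w)p(c))` with additive
  smoothing α = 0.5 propagated consistently to the marginals, natural log
  (the base only rescales rankings, and the ranking is what the feature
  uses). Per class, the k = 20 highest-PMI words among words seen ≥2 times;
  the feature is one count per class (configurable to indicators — whether
  the study used counts, indicators or scores is unstated). Sets are built
  from training folds only, enforced by the interface.
* **Syntactic counts**: count vectors over the fixed 36-tag Penn Treebank
  tagset and 37-relation universal-dependency inventory, produced by bundled
  deterministic rule-based taggers (closed-class lexicon + suffix rules; a
  shallow head heuristic for relations). Taggers are pluggable; a plugged
  tagger emitting an unknown tag raises an error naming it.
* **Concatenation**: `[base | pos | dep | pmi | concept]`, blocks present iff
  enabled; the segment layout is fixed per fitted pipeline.

## Models

* **Majority**: stores the modal training label (ties: lexicographically
  smallest). Its test accuracy equals the majority stratum's test share.
* **Naive Bayes**: multinomial over token counts,
  `P(w|c) = (count(w,c)+1)/(count(c)+|V|)`; unknown test tokens removed;
  all-unknown documents fall back to the prior argmax. Trains on the token
  sequences directly in the harness regardless of the configured base
  representation, because paragraph-vector features can be negative and a
  multinomial event model over them is undefined.
* **Logistic (softmax) regression**: mini-batch SGD on L2-regularized mean
  cross-entropy; batch 32, learning rate 0.1/√t, at most 100 epochs, early
  stop when the epoch-to-epoch loss improvement falls below 1e-4; seeded
  shuffling. The "maximum iterations = 100" setting is read as maximum
  optimizer epochs; batch size, schedule and tolerance are unstated in the
  study and fixed here as defaults.
* **Linear SVM**: primal hinge objective `(1/2)||w||² + C·Σ hinge` with a
  linear kernel, one-vs-rest for multiclass (the study specifies only the
  binary formulation); C defaults to 1.0 (strength unstated). liblinear is
  used as the solver behind this surface; a grid-search oracle over the
  primal objective validates it on small problems.
* All argmax ties break toward the lexicographically smallest label, making
  every prediction deterministic given seed and configuration.

## Splits, selection, evaluation

* **80/20 split**: per-stratum test counts by largest-remainder rounding of
  `0.2 × stratum size` (floors, then +1 to the largest fractional
  remainders until the rounded global total is reached; remainder ties by
  label order). This rule was chosen because it is the allocation that
  reproduces all published test denominators from the published class
  counts: 315/294/99 totals and 21 non-strategies, 99 intrinsic, 17
  preferences. Membership within a stratum is uniform under the split seed.
* **Model selection**: repeated stratified 10-fold cross-validation on the
  training set (3 repeats by default; the study says "repeated" without a
  count), scoring mean fold accuracy with macro-F1 as tie-break and
  candidate order as final tie-break; folds are reduced with a warning when
  the smallest stratum is smaller than the fold count. All feature fitting
  happens inside each training fold. A single-candidate call skips fold
  scoring.
* **Metrics**: accuracy plus per-class and macro precision/recall/F1 with
  the 0-convention for empty denominators; macro averages run over the
  task's gold classes, so a class never predicted still contributes zero F1.
  Report formatting follows the study's print precision (accuracy as a
  percentage to two decimals, F1 to two decimals). Baseline comparisons are
  absolute percentage-point differences.

## Analytic reproduction and its one discrepancy

The majority baselines under the largest-remainder split are 294/315 =
93.33%, 195/294 = 66.33%, 61/99 = 61.62% and 195/315 = 61.9048% → 61.90.
The study prints the first three identically but prints 61.91 for the
fourth; 195/315 cannot round to 61.91 at two decimals, and the same
passage misstates two of its own class counts, so the printed 61.91 is
treated as a rounding slip. The acceptance suite asserts the exact fraction
and agreement with the printed figure to within one unit in the last
printed digit. The task-1 baseline macro-F1 is 2·(294/315)/(1+294/315)/2 =
0.48 at two decimals, matching the cells where learned models collapse to
the majority class.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at the study's corpus
size (1,576 records) for the analytic checks and the SVM + TF-IDF
parameter-recovery runs (three seeds); paragraph-vector training, which is
the one expensive component, is exercised at reduced corpus sizes and is an
opt-in column in the model-comparison driver. Degenerate inputs are handled
explicitly: empty documents vectorize to zeros (TF-IDF) or the seeded
initial vector (paragraph vectors); discriminability 0 makes the
class-conditional content distributions identical by construction (the
keyword pool is never consulted); identical classes yield overlapping PMI
sets without error.

## Known limitations

* Synthetic class signal is lexical and strong at the default
  discriminability, so classifiers near-saturate; conclusions about
  relative model or feature merit on real data do not transfer.
* The rule-based taggers and the shallow dependency heuristic are coarse
  stand-ins for trained syntactic models.
* Concept assignment is keyword triggering, not the study's manual mapping.
* The spelling corrector considers single tokens only; no context.
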