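# Methods

This note documents the models and procedures implemented in `rannote`,
the assumptions behind them, and the design choices made where the
underlying scheme left the design open.

## Annotation data model

Documents are NFC-normalized Unicode strings; entity mentions are typed,
0-based, half-open code-point spans.  The offset convention is not part of
the annotation scheme itself — it was chosen to match the dominant standoff
dialect (brat) and to make read∘write an exact identity, which the tests
rely on.  The schema validator enforces:

- **span integrity** — offsets in range, surface string equal to the text
  slice (hard errors);
- **no overlap or nesting** — any two entity spans are disjoint.  The check
  is a start-sorted sweep that reports exactly the pairs a brute-force
  O(n²) comparison would find;
- **punctuation edges** — a span that starts or ends with punctuation is
  reported at *warning* level only, because symbols with clinical meaning
  (e.g. a unit in a measurement) may legitimately be kept;
- **relation compatibility** — each relation type links a MedicalDiscovery
  with one fixed partner type (BrSy↔BodyPart, TrSy↔TemporalWord,
  IrSy↔Inspection, LrSy↔LaboratoryTest).  Relations are stored head→tail
  with the non-discovery participant as head; the scheme's diagrams draw
  arrows but fix no direction, so this is a package convention.
- **Measurement** is accepted as a valid label with no extra rules; the
  scheme defines no internal structure for it.

Discontinuous entities are assumed not to occur; only contiguous spans are
representable.

## Inter-annotator agreement

One annotator (A) is the reference.  Matching is exact span + type by
default: it is the strictest criterion, it makes greedy counting safe
(exact matches are unique when neither annotation set contains overlapping
spans), and it reproduces the arithmetic of the published consistency
tables from their count columns.  A relaxed overlap criterion (same type,
intersecting spans, each mention used at most once) is available behind a
flag for sensitivity analyses.

P, R and F are computed from integer counts in exact rational arithmetic
and rounded to two decimals only for display; F is the harmonic mean of
the *unrounded* P and R (equivalently F = 200·c/(|A|+|B|)).  Conventions
for empty denominators (P, R, F = 0) are the package's own; the published
tables contain no zero rows.  Several published cells are internally
inconsistent with their own count columns; the package reproduces the rows
that follow from their counts and does not attempt to correct the others.

## Synthetic corpus generator

The generator's purpose is distributional and structural fidelity, not
language modeling: sentences are template renderings (literal connective
fillers around typed entity slots), entity surfaces come from small
built-in per-type CJK lexicons (plus a few romanized laboratory tokens such
as "ALT"), and no grammatical claim is made.  Defaults encode the study
conditions of the corpus being emulated:

- entity-type sampling weights are the corpus distribution counts
  normalized exactly (Body part 22.34% of 66,943, etc.);
- sentences per document are Poisson with mean 54.6 (the documented average
  number of sentences per admit note), clipped to at least 1;
- every template keeps a literal between adjacent slots so that greedy
  longest-match segmentation over the lexicon dictionary never merges two
  entities, which makes gold BIO tags exactly derivable;
- default lexicons are disjoint across types, i.e. unambiguous: the mapping
  from surface to type is learnable, which is what the scaled-down
  recognition experiments require.

Relations link each partner-type mention to the *nearest* MedicalDiscovery
in the same sentence; sentences without a discovery contribute none.

What the generator does **not** emulate: real lexical diversity (a handful
of surfaces per type versus thousands), segmentation ambiguity, section
headings, de-identification artifacts, copy-paste boilerplate, or the
long-tail sparsity that makes rare classes hard in real notes.  Passing
the synthetic experiments therefore demonstrates that the pipeline and the
model are implemented correctly and can learn a learnable corpus — not
that real-corpus F-scores would be matched.

The simulated second annotator perturbs gold mentions independently:
deletion with probability d, type relabeling by a row-stochastic confusion
matrix, single-side boundary shifts of up to `shift_max` characters with
probability s (resampled up to 10 times if the shift would leave the
sentence, overlap another mention, or create a punctuation edge, then
skipped), and spurious mentions added over unannotated spans with expected
count a per gold mention.  Spurious spans never overlap gold spans, so
with only d and a active the expected agreement is closed form: R = 1−d,
P = (1−d)/(1−d+a).  The calibration test checks both at ~5,000 mentions
against 99% binomial intervals.

## Text pipeline

Sentences end after 。！？； or at newlines; terminators stay inside the
sentence, newlines separate.  Segmentation is an injected interface —
the original experiments used jieba, but segmentation errors propagate
into tagging, so the package bundles two deterministic segmenters
(per-character; greedy longest-match over a dictionary) and treats any
span-producing callable as valid.  Entity spans that straddle a token
boundary are a declared policy decision: `error` by default,
`snap-outward` (widen to token boundaries, log a warning) on request.

BIO is used exactly as specified (no BIOES variant).  At decode time an
`I-X` following `O`, the sentence start, or a different type is repaired to
`B-X` — necessary because the CRF's transitions are learned, not
constrained, so any tag sequence can be emitted; the repair matches the
effective behaviour of the standard conlleval script.

Batches pad sentences with PAD (index 0) to the batch maximum length and
pad each word's characters at the end to the longest word in the batch,
floored at 4 so every CNN kernel width fits.  Masked positions contribute
nothing to loss, gradients or decoding.

## Tagger

Emissions are log-softmax rows over the tag set produced by
word-embedding → char encoder → gate → BiLSTM → linear; the CRF adds
learned transition scores plus BOS/EOS boundary vectors (modeled as extra
transition rows, not emitted tags).  The training objective — not written
down in the original description — is the standard sequence negative
log-likelihood with the partition function from the forward algorithm:
this is the only standard reading consistent with "unary tag score" +
learned transitions + Viterbi decoding.  Viterbi ties break toward the
lower tag index (argmax takes the first maximum); the tag order is fixed
(O first, then B-/I- pairs sorted by type name), so decoding is fully
deterministic.

The gate is a per-dimension vector (the formula uses elementwise
products); a scalar-gate variant is available behind `scalar_gate` since
the formulation is ambiguous on this point.  "No attention" is implemented
as plain concatenation of word and character vectors; whether the original
ablation meant concatenation or summation is ambiguous, and concatenation
was chosen.

### Numerical and training choices

- **Implementation** is pure numpy with hand-written backpropagation,
  verified against finite differences (all layers) and exhaustive path
  enumeration (CRF, tolerance 1e-6 at n ≤ 6 tokens, T ≤ 5 tags).
- **Fixed regime** (as documented for the original system): batch size 20,
  Adadelta (ρ = 0.95, ε = 1e-6, lr multiplier 1.0), global-norm gradient
  clipping at 5.0, dropout 0.5 on the combined embedding and the BiLSTM
  output, fine-tuned word and character embeddings, early stopping on
  development entity F when enabled.
- **Free sizes** (never stated in the original description, chosen for
  CPU-scale corpora): word dim 48, char dim 24, 16 CNN filters per kernel
  width (output 48 = word dim, as the gate requires), BiLSTM hidden 48 per
  direction, gate hidden 32.  Larger dims (e.g. 300) are plain config
  changes; the uniform init bound √(3/dim) equals 0.1 at dim 300.
- **Initialization**: embeddings and weight matrices uniform in
  ±√(3/fan-in); LSTM forget-gate bias 1; PAD rows frozen at zero;
  CRF transitions start at zero.
- **Batch normalization** is optional and off by default: its placement
  ("on hidden units in all layers") is ambiguous, so it is applied after
  the char-CNN pooling and after the pre-CRF linear layer, with statistics
  over the tokens flowing through the layer.  On the tiny synthetic
  corpora used here its estimates are too noisy to help, hence the
  default.
- **Determinism**: one seed is split (via `SeedSequence`) into an
  initialization stream and a training stream (shuffling + dropout);
  two runs with the same seed produce bit-identical parameters in
  single-threaded execution.
- **Degenerate inputs**: empty corpora, empty sentences, all-masked rows,
  and early stopping without a dev set raise immediately.

### Checkpoints and pretrained embeddings

Checkpoints are a single `.npz` archive embedding the config (JSON), the
vocabulary (text) and every parameter tensor plus batch-norm running
statistics; loading reproduces predictions bit-identically on the same
platform.  Pretrained vectors use the word2vec text dialect
(`<count> <dim>` header); symbols missing from the file keep their random
initialization, and loaded rows are fine-tuned like any other.

## Evaluation

Entity-level, CoNLL-2003 style: entities are extracted from gold and
(repaired) predicted tag sequences and a prediction is correct only on
exact span and type; counts are pooled over types for the overall row, and
over folds for cross-validation (micro-averaging).  The evaluator
deliberately shares counting semantics with the IAA engine — gold as
annotator A, prediction as annotator B — and the tests verify exact
agreement between the two, as well as agreement with an independent
re-implementation of conlleval chunk extraction on fuzzed tag sequences.

## Problem sizes used in the checked experiments

The original headline results (best F 91.08%) were obtained on a
255-document hospital corpus that is not publicly deposited, so they are
not reproduced.  The substitute experiments run on generated data at
sizes chosen to exercise the full pipeline comfortably on one CPU:

- capacity check: 30 sentences, 200 epochs, no dropout — training-set
  entity F reaches 100;
- scaled-down recognition experiment: 200 documents at ~4 sentences each
  (~780 sentences, ~1,550 mentions), 5-fold document-level
  cross-validation, 6 epochs per fold, dropout 0.2 — micro F ≈ 99 against
  a ≥ 90 requirement (unambiguous lexicons make the mapping learnable;
  residual errors concentrate in rare types, mirroring the real corpus's
  behaviour on small classes);
- perturbation calibration: ~5,200 mentions, d = 0.2, a = 0.1.

## Known limitations

- The tagger is CPU-bound pure numpy; it is meant for method validation
  and small corpora, not production-scale training.
- No relation *prediction* is included: relations are modeled, validated
  and generated, but the recognizer tags entities only.
- Word segmentation quality is the user's responsibility via the segmenter
  interface; the bundled segmenters are deterministic baselines.
- No support for discontinuous or nested entities, BIOES schemes, or
  de-identification.
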