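# Methods

This note records the modelling choices behind the package: what the
insertion methods and their evaluation actually compute, what the
synthetic corpus and the mock backend do and do not emulate, and where the
design was genuinely open.

## Insertion methods and truncation

All methods assemble a model input from a note, a cloze template, and a
token budget `available = model_max − template_tokens − special_tokens`,
so an assembled input can never exceed the model limit.

**Sentence units.** Sentences are delimited by `. ! ?` followed by
whitespace, or by a newline. Clinical notes are line-structured; a
deterministic rule that reconstructs the original text exactly (spans plus
whitespace gaps) matters more here than linguistic accuracy, and the
splitter sits behind a small contract so it can be replaced. Abbreviations
are not special-cased.

**Keyword flagging** is case-insensitive plain-substring matching.
Keyword lists deliberately include sub-words ("osteo" must hit
"osteoarthritis"), which rules out word-boundary semantics; no stemming is
applied. Keywords are stored lowercase. Only the *first* flagged sentence
anchors the split, even when later flags exist.

**Proportional truncation.** With chunks `a` (before and including the
anchor sentence) and `b` (after it) and `excess = |a|+|b|−available`,
KOTI removes `round_half_up(excess·|a|/(|a|+|b|))` tokens from the *front*
of `a` and the remainder from the *end* of `b`, capped at each chunk's
length with overflow pushed to the other chunk. Exact total removal is
guaranteed and the proportionality error is at most one token; an
enumeration oracle (all splits of the excess, closest-to-ideal wins, ties
to the larger left share) agrees exhaustively for all chunk lengths ≤ 40
and budgets ≤ 60. Rounding direction and cap behaviour are
implementation-defined choices; half-up with remainder-to-`b` was chosen
for determinism and symmetry of error.

Strict proportionality may, for extreme length ratios, cut into the
flagged sentence itself; no protective override is applied, because plain
proportionality is the defining behaviour of the method. Chunks are
tokenized independently and concatenated at the token level — a seam
artifact is possible with subword tokenizers and accepted, because removal
counts must be exact in tokens.

**Fallback.** A note without any keyword match uses the naive layout
(full text tail-truncated, template appended) in every method, flagged
`fallback=true`. For the decoder variant the fallback keeps the decoder
template (no mask token).

**Offsets.** `KOTI_OFFSET` moves the split to the end of sentence
`first_flag + offset`, clamped to the note's sentence range; the effective
(post-clamp) offset is recorded. Offset 0 reproduces KOTI exactly.

## Verbalizer

Class probabilities are a single softmax restricted to the label-word
logits at the scoring position. No corpus-prior calibration is applied:
the "normalization" that some verbalizer designs add before the softmax is
not separately specified here, and the plain restricted softmax is the
minimal reading. Label words must be single tokens under the backend
tokenizer; multi-token words are a hard error rather than first-token or
mean pooling, because silent pooling scores a different word than the
task author intended. Argmax ties resolve to the earliest class in the
task's class order — which is why the synthetic task lists `unknown`
first: a no-signal tie then lands on the no-evidence class, matching the
clinical semantics of an unmentioned finding.

## Synthetic corpus

The generator emulates exactly one property of real clinical corpora: the
evidence for the label is a single sentence at an arbitrary position
inside a long, mostly administrative note. Defaults (the study
conditions): 300 notes; classes unknown/yes/no with prevalence
0.2/0.4/0.4; 10–18 whitespace tokens per sentence; evidence position
uniform; 70% of notes exceed a 512-token budget; 10% of non-unknown notes
contain one distractor sentence (a task keyword without a cue).

Two generator choices deserve emphasis:

- **Over-budget notes target 1.2–3.0× the budget.** Discharge summaries
  that exceed a 512-token limit typically exceed it severalfold (roughly
  three model passes per note in sliding-window approaches). Stopping just
  past the budget would make tail truncation nearly harmless and the
  baseline artificially strong.
- **Distractors are per note, not per sentence.** One false-anchor
  sentence per note with probability `distractor_rate` keeps keyword
  matches predominantly informative — the premise of anchoring on
  keywords at all — while still exercising the first-flag rule against
  false anchors. A per-sentence rate on 50–100-sentence notes would plant
  many distractors per note, and the first flag would almost always be an
  early false anchor: every keyword-based method then degenerates towards
  head truncation and the comparison measures noise, not position.

Cue, keyword and filler vocabularies are validated disjoint (including
substring collisions with keywords), so a note's label is re-derivable
from its text alone; `oracle_label` checks this provenance and raises on
tampering. Unknown-class notes contain no keywords, hence always exercise
the fallback path. The generator controls the over-budget fraction per
note by construction, so the realized fraction tracks the target closely.
What the corpus does *not* emulate: clinical language, section structure,
negation scope, label noise, or multi-evidence notes — conclusions from
these simulations are about truncation and position geometry, not about
language understanding.

## Mock backend

The mock operationalizes the premise that a model's usable signal decays
with the distance between the scoring position and the class-revealing
text. Each class has a disjoint cue lexicon; the logit of a class's label
word is `max(0, base − decay·d)` for the nearest cue at token distance
`d ≤ window`, else 0. Defaults: `base=4`, `decay=0.02`, `window=150` — a
hard visibility horizon at 150 tokens with signal 1.0–4.0 inside it.
Scoring is deterministic and stateless: identical inputs give bit-identical
logits, so any F1 difference between methods is attributable to which
inputs they assemble.

An optional `noise_sd` adds a reproducible per-(note, class) N(0, σ)
perturbation (seeded, hash-derived from the note id, identical across
rescoring and across methods for the same note). With noise, argmax
accuracy becomes a smooth function of the signal margin instead of a hard
threshold, which lets retention effects at long range show up gradually;
the shipped studies use the noiseless default, where the picture is
sharper: a method scores a note correctly iff it keeps a cue within the
horizon of its template.

The trainable backend is a deliberately small cloze scorer, not a
transformer: proximity-weighted embedding pooling around the mask
(weights `∝ exp(−|i−m|/τ)`, τ=16), LayerNorm, one tanh layer, vocabulary
projection; float64 throughout, exactly reproducible given a seed.
Fine-tuning minimizes cross-entropy of the restricted softmax against the
gold class with AdamW (weight decay 0.01 on weights only; biases and
normalization gain/bias are excluded by a name predicate, and the
optimizer exposes the decayed-parameter list for audits). The default
learning rate 0.002 (batch 8) was chosen for smooth, monotone convergence
on this model scale; larger rates converge faster but oscillate once the
loss is near zero. No schedule or early stopping is applied — epochs are
fixed by config, and hyper-parameters not pinned down here are left to
the random-search module.

## Evaluation protocol and statistics

Few-shot runs resample the training set (balanced k per class,
size-matched random, or fixed total; without replacement; run *i* draws
its RNG from `(seed, i)`), fine-tune a fresh backend copy, and evaluate
on the remaining pool; zero-shot is a single untrained run over the whole
pool. Binary tasks are summarized by the positive class's F1, multiclass
tasks by macro-F1; degenerate 0/0 precision/recall ratios score 0.

Comparisons report ΔF1 and percent change (undefined and reported as
missing when the baseline mean is 0), p-values from a two-sided paired
t-test, and Holm–Bonferroni step-down decisions. Degenerate pairings have
documented conventions: identical vectors give p=1; a constant nonzero
difference has an infinite t statistic and returns p=0 with a warning.
Two pairing axes exist because published comparisons mix them: per-task
tests pair the repeated runs (the Holm family), and a separate overall
row pairs per-task means. For a five-comparison family at α=0.05 the most
stringent Holm threshold is 0.01.

## The shipped studies

`zero_shot_position_study` is the canonical protocol behind both the test
suite and `scripts/acceptance.py`:

- **Direction of effect** (study conditions above, 10 corpus seeds):
  mean zero-shot macro-F1 ordering KOTI ≥ STI-k ≥ STI-s, with the
  KOTI−STI-s gap large (≈0.6 at the defaults). KOTI wins through both
  retention and proximity; STI-k beats STI-s through retention alone.
- **Offset decay** (same conditions, distractors off, offsets 0/±6/±12):
  F1 declines monotonically with template distance from the keyword
  sentence. Distractors are excluded here because a false anchor always
  *precedes* the evidence sentence, so positive offsets would partially
  rescue misanchored notes and confound the pure distance effect.
- **Fine-tuning smoke test**: the tiny masked LM on 40 separable
  synthetic examples, 10 epochs — epoch-mean loss decreases monotonically
  to ~1e-3, and the decay-exclusion audit finds no bias/normalization
  parameter regularized.

Passing these shows the geometry of truncation and template position is
implemented correctly and drives performance in the direction the method
predicts *when evidence is sparse, local and keyword-adjacent*; it says
nothing about real language models or real notes, where keyword precision,
evidence diffusion and domain shift all matter.

## Known limitations

- The sentence splitter treats every newline as a boundary; wrapped
  paragraphs produce over-segmentation (harmless for splitting, since
  spans reconstruct the text exactly).
- Substring keyword matching ("oa") can flag unrelated words ("coat");
  that is the documented cost of sub-word anchors, borne by design.
- The mock whitespace tokenizer assigns ids in first-seen order; a
  tokenizer must therefore see the corpus (and label words) before being
  frozen for a fixed-vocabulary model.
- `random_search` takes an injectable evaluation callable; dominance
  checks require a trainable backend, since fine-tuning the mock is a
  no-op by contract.
- Real-checkpoint adapters require the optional `transformers`/`torch`
  dependencies and are not covered by the test suite.
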