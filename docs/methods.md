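# Methods

## Problem and model

The package classifies picture-description transcripts (the Cookie Theft
task of the Boston Diagnostic Aphasia Examination) as produced by people
with Alzheimer's disease (AD) or by cognitively healthy controls (CTRL).
Such transcripts carry no explicit opinion words; the class signal is
distributional — hesitation fillers, pronoun substitution for content
nouns, reduced informational coverage, shorter descriptions — so the
classifier must weigh words and sentences unequally.

The model is a two-level (hierarchical) attention network. For a document
of sentences s_1..s_L, each sentence a sequence of tokens w_{i1}..w_{iT}:

1. **Embedding** x_it = W_e w_it.
2. **Word encoder**: a bidirectional GRU over each sentence,
   h_it = [h→_it, h←_it] ∈ R^{2u}.
3. **Word attention**: s_it = tanh(W_w h_it + b_w),
   m_it = softmax_t(s_itᵀ t_w), sentence vector p_i = Σ_t m_it h_it.
4. **Sentence encoder**: a bidirectional GRU over p_1..p_L giving
   h_i ∈ R^{2u}.
5. **Sentence attention**: same mechanism with its own parameters
   (W_s, b_s, context s_w), giving weights m_i and document vector
   p = Σ_i m_i h_i.
6. **Classifier**: t = softmax(w p + b) over {CTRL, AD}; training loss is
   the summed negative log-likelihood of the true labels,
   L = −Σ_d log t_{d,j(d)}.

The GRU cell uses the standard gate formulation (update gate z, reset
gate r, candidate tanh state with the reset gate applied inside the
recurrent term); see the `han_core` module docstring for the exact
equations. Word-level and sentence-level attention are two independent
parameter sets: sharing one projection across levels with different
semantics would be an unusual design, so the package keeps them separate
(both use projection dimension `attn_dim`).

Everything — forward pass and analytic backward pass — is implemented in
numpy. Gradient correctness is not assumed: the test suite compares every
parameter group against central finite differences in double precision on
a tiny configuration (embedding 4, hidden 3, attention 2, one document of
2 sentences × 3 words) and requires relative error below 1e-4.

## Reference training configuration

`TrainConfig` defaults:

| parameter        | default | origin |
|------------------|---------|--------|
| `gru_units` u    | 100     | reference protocol |
| `attn_dim` a     | 50      | reference protocol (word level; the sentence level reuses it, configurable) |
| `embed_dim` d    | 100     | reference protocol (GloVe 100-d when a file is supplied) |
| `epochs`         | 10      | fixed-epoch protocol; best epoch by validation accuracy, earliest wins ties |
| `learning_rate`  | 0.01    | Adam |
| `dropout`        | 0.35    | inverted dropout on embedding output, word hidden pairs, sentence vectors, document vector |
| `init_std`       | 0.1     | all weights ~ normal(0, 0.1); biases zero (see below) |
| `batch_size`     | 16      | package choice: small corpus, stable gradients |
| `grad_clip`      | 5.0     | package choice: Adam at lr 0.01 on GRUs can spike; clipping is logged |
| `min_count`      | 1       | no vocabulary pruning on small corpora |
| `l_max`/`t_max`  | None    | 95th percentile of the training split's sentence/word counts, recomputed per run |
| `dtype`          | float32 | float64 available; all numeric tests use float64 |

Deviations adopted as package design choices: the reference protocol
states random initialization for biases, but zero biases are more stable
on small corpora and are used here; the protocol is silent on GRU and
classifier weight initialization, which this package draws from the same
normal(0, 0.1). Embedding rows are fine-tuned during training
(`trainable=True`) since pretrained vectors only *initialize* W_e; a flag
allows freezing. Probabilities are clamped at 1e-12 inside the loss's
log (logged when triggered). All randomness (init, dropout, shuffling,
splits) flows from seeded `numpy` generators, so (config, seed, corpus)
fully determine every reported number, bitwise.

## Evaluation protocols

Two protocols are supported, mirroring common practice on this corpus
family:

- **Fixed split**: stratified 8:1:1 train/validation/test with
  largest-remainder rounding per class (498 documents give 398/50/50; no
  standard rounding reproduces a 400/50/48 split, so exact historical
  splits cannot be reconstructed). `HanModel.fit()` uses this.
- **Five-fold cross-validation**: stratified, globally balanced within
  one document; within each fold, 1/9 of the training portion (stratified)
  is carved out as the validation set for epoch selection.
  `HanModel.fit_cv()`; aggregate metrics are the unweighted mean of fold
  metrics, with pooled-confusion metrics also reported.

An optional `patient_id` manifest column lets splits keep all visits of
one patient on the same side, since repeated visits otherwise leak
identity across sets.

Metrics are accuracy, precision, recall and F1 with AD as the positive
class. Zero-denominator metrics are reported as *undefined with a
reason*, never coerced to 0.

## Ablations

`ablate_variant` replaces the named attention level ("no_word_attn" /
"no_sentence_attn") with a uniform average over valid positions; nothing
else changes, and ablated attention parameters receive zero gradient.
This isolates the contribution of each attention level.

## CHAT preprocessing

`chat_io` reduces CHAT (.cha) files to pure participant text: only `*PAR`
tiers are kept by default (the classified language is the patient's),
dependent tiers (`%mor`, `%gra`, ...) are dropped, and inline codes are
removed by the single editable rule table `STRIP_RULES` (bracketed
retracing/error codes, `&`-events, `@`-form markers keeping the stem,
pause symbols, angle-bracket scope markers keeping the words, shortening
parentheses). Text is NFC-normalized and lowercased; each utterance
becomes one sentence. The exact rule inventory is a package choice — the
cleaning goal ("pure text") is standard but no canonical rule list
exists — hence the one-table design so other CHAT dialects can be
matched. Sentence-final punctuation tokens are retained (they carry
utterance-boundary signal) but excluded from the marker lexicons.

For plain text, a rule-based splitter (break on `.?!` + whitespace) and a
word/punctuation tokenizer are the defaults; both are pluggable, so an
external tokenizer such as a CoreNLP wrapper can be substituted without
changing any other component.

## Synthetic corpus generator

Access to the real clinical corpus is restricted, so `synthgen` generates
stand-ins whose class signal lives in exactly the token statistics listed
above. Per document: sentence count ~ round(normal) per class
(CTRL 11±2, AD 6±1.5), words per sentence ~ round(normal(8, 2), min 3).
Filler slots are drawn per token at the class rate (AD 0.15, CTRL 0.01),
so realized filler frequency equals the configured rate. Each document
mentions a fraction of the 23-word seed lexicon of a complete description
(AD 0.3, CTRL 0.8); one occurrence per covered word is protected, free
slots repeat covered seed words with probability 0.35 or draw from 200
pseudo-word distractors (regenerated once per seed), and unprotected
seed-word occurrences are replaced by "he"/"she" at the class pronoun
rate (AD 0.30, CTRL 0.02). Every planted filler and pronoun position is
recorded, giving exact marker ground truth. The default parameterization
lives in `hanscribe/data/synth_default.json`, shared by tests, the
acceptance script and documentation.

Sentences are flat token sequences ending in "." — no natural syntax, no
disfluency timing, no discourse semantics. The model consumes token
statistics only, so this keeps the generative ground truth exact; it also
means that passing the synthetic benchmarks demonstrates that the
implementation can learn and localize distributional class markers, not
that it reaches any particular accuracy on real clinical speech.

## Attention scoring and visualization

Word weights are normalized by sentence weights (m_i · m_it) so only
important words in important sentences are emphasized; the products sum
to 1 per document. `marker_attention_score` sums these products over the
planted marker positions; under uniform attention it equals the marker
token fraction, so the ratio of the two measures enrichment. The HTML
report shades tokens green by normalized weight and draws a red sentence
bar by sentence weight, both rescaled by the per-document maximum
(per-document, not global, so short documents remain readable — stated in
the report header). Rendering is deterministic and checked against a
golden file.

## Benchmark problem sizes and numerical choices

The standard benchmark (`experiments.synthetic_benchmark`, also run by
`scripts/acceptance.py`) uses 200 documents per class, three seeds, and
5-fold cross-validation at the reference configuration for the full model
and both ablations. Expected outcomes at the default parameterization:
full-model mean accuracy ≥ 0.95 and marker-attention enrichment ≥ 2× the
uniform baseline (observed ≈ 3×).

Numerical details: numerically stable softmax (max subtraction)
everywhere; attention over fully masked rows yields zero weights and a
zero pooled vector (only reachable for padded sentences, which the
sentence mask excludes); mask-gated GRU state updates make padded
positions exactly inert, verified by a padding-invariance test at 1e-6;
tie-break in model selection is the earliest best epoch; batches are
trimmed to their longest document so padding never grows with the corpus.

## Known limitations

- Templated synthetic text cannot certify real-world clinical accuracy;
  published accuracies on the restricted corpus are not comparable to the
  synthetic benchmark numbers.
- The GRU/attention equations are single-layer as specified; no LSTM
  swap, no multi-class output, no subword tokenization, no contextual
  embeddings.
- CPU-only numpy implementation: practical for corpus sizes in the
  hundreds of documents, not for large-scale pretraining.
- The rule-based sentence splitter is deliberately naive (reliable for
  transcripts; not for text rich in abbreviations).
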