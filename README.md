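# hanscribe

Hierarchical attention networks for classifying picture-description
transcripts as Alzheimer's disease (AD) vs. cognitively healthy control
(CTRL).

Transcripts of the Cookie Theft picture-description task carry no
explicit sentiment: the diagnostic signal is distributional — hesitation
fillers ("uh", "um"), pronouns standing in for content nouns, reduced
coverage of the picture's content lexicon, shorter descriptions. This
package implements a two-level attention network for that document-level
"implicit" classification problem, together with CHAT-format
preprocessing, the training and cross-validation protocol, attention
visualization, and a synthetic-corpus generator so that everything is
testable without access-restricted clinical data.

## Model

For a document of sentences s_1..s_L with tokens w_{i1}..w_{iT}:

    x_it = W_e w_it                      token embedding
    h_it = [GRU→(x_it), GRU←(x_it)]      bidirectional word encoder
    m_it = softmax_t( tanh(W_w h_it + b_w)ᵀ t_w )    word attention
    p_i  = Σ_t m_it h_it                 sentence vector
    h_i  = [GRU→(p_i), GRU←(p_i)]        bidirectional sentence encoder
    m_i  = softmax_i( tanh(W_s h_i + b_s)ᵀ s_w )     sentence attention
    p    = Σ_i m_i h_i                   document vector
    t    = softmax(w p + b)              class probabilities {CTRL, AD}

trained with the summed negative log-likelihood, Adam (lr 0.01), dropout
0.35, 10 fixed epochs with best-epoch selection on validation accuracy.
The hierarchical attention products m_i·m_it sum to 1 per document and
indicate which words in which sentences drove the decision.

The network and its analytic gradients are implemented in numpy and
verified against central finite differences (relative error < 1e-4) in
the test suite; see `docs/methods.md` for the full model account,
parameter table and design choices.

## Worked example

```python
from hanscribe import HanModel, SynthConfig, TrainConfig, generate_corpus

corpus = generate_corpus(SynthConfig.default(n_docs_per_class=50, seed=0))
model = HanModel(corpus.transcripts, config=TrainConfig(seed=0))
res = model.fit()          # stratified 8:1:1 split, 10 epochs
print(res.summary())
```

prints

```
Hierarchical attention network — fit summary
==============================================
protocol        fixed-split 8:1:1
documents       100
vocabulary      230
L_max / T_max   14 / 12
GRU units       100   attention dim 50
epochs          10   best epoch 1
dropout         0.35   lr 0.01
ablation        none
validation accuracy by epoch: 1.000 1.000 1.000 1.000 1.000 1.000 1.000 1.000 0.900 1.000
----------------------------------------------
held-out test metrics:
n = 10
confusion  TP=4 FP=0 FN=1 TN=5
accuracy   0.9000
precision  1.0000
recall     0.8000
f1         0.8889
```

The confusion row says that of the 10 held-out documents, 4 AD documents
were recognized (TP), one was missed (FN), and all 5 controls were
correct (TN); accuracy is 9/10. `res.attention_report(docs, "report.html")`
renders the per-token attention heatmap (green = word weight, red bar =
sentence weight) with a JSON sidecar of all weights, and
`model.fit_cv(k=5)` runs stratified five-fold cross-validation instead of
the fixed split.

Real CHAT transcripts enter through `hanscribe.chat_io`:

```python
from hanscribe import chat_io
doc = chat_io.strip_annotations(chat_io.read_chat_file("patient.cha"))
```

which keeps only `*PAR` tiers and strips all inline CHAT codes
(`[//]`, `&=laughs`, `word@o`, ...) down to pure lowercase text.

A CLI covers the same paths:

```sh
hanscribe simulate --n-docs 200 --seed 0 --out corpus.jsonl
hanscribe train    --corpus corpus.jsonl --out run/
hanscribe crossval --corpus corpus.jsonl --folds 5 --out cv/
hanscribe visualize --corpus corpus.jsonl --checkpoint run/checkpoint.npz --out report.html
```

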