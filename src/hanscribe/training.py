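"""Initialization, optimization, data splitting and cross-validation.

Training follows a fixed-epoch protocol: train for ``epochs`` epochs with
Adam, evaluate on a validation set after every epoch, and keep the
parameters from the epoch with the highest validation accuracy (earliest
epoch wins ties).  Two evaluation protocols are supported: a fixed
stratified 8:1:1 train/validation/test split, and stratified k-fold
cross-validation where a validation subset for epoch selection is carved
out of each fold's training portion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import han_core, textprep
from .errors import ConfigError, DivergenceError, SplitError
from .evaluation import MetricReport, evaluate, mean_report, pooled_report
from .han_core import AttentionParams, GruParams, HanParams
from .textprep import EmbeddingMatrix, Vocabulary
from .transcripts import LABELS, CleanTranscript

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyper-parameters; defaults are the reference training configuration.

    ``gru_units``, ``attn_dim``, ``embed_dim``, ``epochs``, ``learning_rate``,
    ``dropout`` and ``init_std`` carry the published protocol values; batch
    size, gradient clipping and the validation fraction used inside
    cross-validation are this package's own choices.
    """

    gru_units: int = 100
    attn_dim: int = 50
    embed_dim: int = 100
    epochs: int = 10
    learning_rate: float = 0.01
    optimizer: str = "adam"
    dropout: float = 0.35
    init_std: float = 0.1
    batch_size: int = 16
    seed: int = 0
    ablation: str = "none"
    min_count: int = 1
    l_max: Optional[int] = None        # None -> 95th percentile of train split
    t_max: Optional[int] = None
    length_percentile: float = 95.0
    grad_clip: float = 5.0
    val_fraction: float = 1.0 / 9.0    # carved from the train portion in CV
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError(f"dropout must be in [0,1), got {self.dropout}")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ConfigError("learning_rate must be in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1 or self.gru_units < 1:
            raise ConfigError("epochs, batch_size, gru_units must be >= 1")
        if self.ablation not in han_core.ABLATIONS:
            raise ConfigError(f"unknown ablation {self.ablation!r}")
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is supported")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def ablate_variant(config: TrainConfig, which: str) -> TrainConfig:
    """Return a config whose named attention level is replaced by a uniform
    average over valid positions; everything else unchanged."""
    if which not in ("no_word_attn", "no_sentence_attn"):
        raise ConfigError(f"unknown ablation variant {which!r}")
    return replace(config, ablation=which)


@dataclass
class FoldResult:
    fold_index: int
    best_epoch: int
    val_trace: list[float]
    metrics: Optional[MetricReport] = None
    attention: Optional[list] = None         # AttentionRecord per test doc
    predictions: Optional[list[str]] = None
    test_doc_ids: Optional[list[str]] = None


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_params(config: TrainConfig, vocab: Vocabulary,
                embeddings: Optional[EmbeddingMatrix] = None,
                seed: Optional[int] = None) -> HanParams:
    """Draw all weights from normal(0, init_std); biases start at zero.

    The embedding matrix is copied if given, otherwise drawn from the same
    distribution.  All randomness flows from one seeded generator so that
    identical (config, vocab, seed) give identical parameters.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dt = config.np_dtype
    d, u, a = config.embed_dim, config.gru_units, config.attn_dim
    std = config.init_std

    if embeddings is None:
        W = rng.normal(0.0, std, size=(len(vocab), d)).astype(dt)
        embeddings = EmbeddingMatrix(weights=W, dim=d, trainable=True)
    else:
        if embeddings.dim != d:
            raise ConfigError(
                f"embedding dim {embeddings.dim} != config.embed_dim {d}")
        embeddings = EmbeddingMatrix(
            weights=embeddings.weights.astype(dt).copy(),
            dim=embeddings.dim, trainable=embeddings.trainable)

    def gru(d_in: int) -> GruParams:
        return GruParams(
            W=rng.normal(0.0, std, size=(d_in, 3 * u)).astype(dt),
            U=rng.normal(0.0, std, size=(u, 3 * u)).astype(dt),
            b=np.zeros(3 * u, dtype=dt),
        )

    def attn() -> AttentionParams:
        return AttentionParams(
            W=rng.normal(0.0, std, size=(2 * u, a)).astype(dt),
            b=np.zeros(a, dtype=dt),
            u_ctx=rng.normal(0.0, std, size=a).astype(dt),
        )

    return HanParams(
        embedding=embeddings,
        word_fwd=gru(d), word_bwd=gru(d),
        sent_fwd=gru(2 * u), sent_bwd=gru(2 * u),
        word_attn=attn(), sent_attn=attn(),
        classifier_w=rng.normal(0.0, std, size=(2, 2 * u)).astype(dt),
        classifier_b=np.zeros(2, dtype=dt),
    )


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: HanParams, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 grad_clip: float = 0.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr in params.flat()}
        self.v = {name: np.zeros_like(arr) for name, arr in params.flat()}

    def step(self, params: HanParams, grads: dict[str, np.ndarray]) -> None:
        if self.grad_clip > 0:
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if gnorm > self.grad_clip:
                logger.debug("clipping gradient norm %.3f -> %.3f",
                             gnorm, self.grad_clip)
                scale = self.grad_clip / gnorm
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, arr in params.flat():
            if name == "embedding" and not params.embedding.trainable:
                continue
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            arr -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
        params.embedding.weights[0, :] = 0.0  # PAD row stays zero


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - sizes[i],
                   reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def make_split(corpus: Sequence[CleanTranscript],
               ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = 0,
               group_by_patient: bool = False,
               ) -> tuple[list[int], list[int], list[int]]:
    """Stratified train/validation/test index split.

    Per-class allocation uses largest-remainder rounding, so per-set class
    proportions stay within one document of the global proportions.  With
    ``group_by_patient`` no patient's documents span two sets.
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios) \
            or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must be 3 positives summing to 1: {ratios}")
    rng = np.random.default_rng(seed)
    sets: tuple[list[int], list[int], list[int]] = ([], [], [])

    if group_by_patient:
        groups: dict[str, list[int]] = {}
        for i, doc in enumerate(corpus):
            key = doc.patient_id if doc.patient_id is not None else f"__solo_{i}"
            groups.setdefault(key, []).append(i)
        keys = sorted(groups)
        rng.shuffle(keys)
        targets = _largest_remainder(len(corpus), ratios)
        filled = [0, 0, 0]
        for key in keys:
            # place each patient where the deficit is largest
            deficits = [targets[s] - filled[s] for s in range(3)]
            s = int(np.argmax(deficits))
            sets[s].extend(groups[key])
            filled[s] += len(groups[key])
    else:
        for label in LABELS:
            idx = [i for i, d in enumerate(corpus) if d.label == label]
            idx = list(rng.permutation(idx))
            sizes = _largest_remainder(len(idx), ratios)
            start = 0
            for s, size in enumerate(sizes):
                sets[s].extend(int(i) for i in idx[start:start + size])
                start += size

    for s, name in zip(sets, ("train", "validation", "test")):
        labels_here = {corpus[i].label for i in s}
        if len(labels_here) < 2:
            raise SplitError(
                f"{name} split received documents of only {labels_here}")
    return tuple(sorted(s) for s in sets)  # type: ignore[return-value]


def stratified_kfold(corpus: Sequence[CleanTranscript], k: int,
                     seed: int = 0) -> list[list[int]]:
    """Stratified partition into k folds, globally balanced within 1 doc."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    extras: list[int] = []  # indices left over after equal per-class split
    for label in LABELS:
        idx = [i for i, d in enumerate(corpus) if d.label == label]
        if len(idx) < k:
            raise SplitError(f"class {label} has fewer documents than folds")
        idx = list(rng.permutation(idx))
        base = len(idx) // k
        for f in range(k):
            folds[f].extend(int(i) for i in idx[f * base:(f + 1) * base])
        extras.extend(int(i) for i in idx[k * base:])
    # distribute leftovers to the currently smallest folds
    for i in extras:
        f = int(np.argmin([len(fold) for fold in folds]))
        folds[f].append(i)
    return [sorted(f) for f in folds]


def _carve_validation(corpus, train_idx, fraction, seed):
    """Stratified validation subset from a training index list."""
    rng = np.random.default_rng(seed)
    val: list[int] = []
    for label in LABELS:
        idx = [i for i in train_idx if corpus[i].label == label]
        idx = list(rng.permutation(idx))
        n_val = max(1, int(round(fraction * len(idx))))
        val.extend(int(i) for i in idx[:n_val])
    val_set = set(val)
    train = [i for i in train_idx if i not in val_set]
    if not train:
        raise SplitError("validation carve left no training documents")
    return sorted(train), sorted(val)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _trim_batch(batch):
    """Drop all-pad sentence/word columns so each batch is as small as its
    longest document; outputs are invariant to this (masking invariance)."""
    l_used = int(batch.sentence_mask.sum(axis=1).max())
    t_used = int(batch.word_mask.sum(axis=2).max())
    return textprep.EncodedBatch(
        token_ids=batch.token_ids[:, :l_used, :t_used],
        word_mask=batch.word_mask[:, :l_used, :t_used],
        sentence_mask=batch.sentence_mask[:, :l_used],
        labels=batch.labels,
        doc_ids=batch.doc_ids,
    )


def predict(params: HanParams, docs: Sequence[CleanTranscript],
            vocab: Vocabulary, l_max: int, t_max: int,
            batch_size: int = 64, ablation: str = "none"):
    """Deterministic inference.

    Returns (labels, probabilities (n, 2), attention records).
    """
    labels: list[str] = []
    probs = []
    records = []
    for start in range(0, len(docs), batch_size):
        chunk = docs[start:start + batch_size]
        batch = _trim_batch(textprep.encode_batch(chunk, vocab, l_max, t_max))
        outs = han_core.forward_document(batch, params, dropout_rate=0.0,
                                         training=False, ablation=ablation)
        for o in outs:
            probs.append(o.class_probabilities)
            labels.append(LABELS[int(np.argmax(o.class_probabilities))])
            records.append(o.attention)
    return labels, np.asarray(probs), records


def train(corpus: Sequence[CleanTranscript], config: TrainConfig,
          train_idx: Optional[Sequence[int]] = None,
          val_idx: Optional[Sequence[int]] = None,
          vocab: Optional[Vocabulary] = None,
          embeddings: Optional[EmbeddingMatrix] = None,
          ) -> tuple[HanParams, FoldResult, dict]:
    """Train with fixed epochs and validation-accuracy model selection.

    If no index sets are given, a stratified 8:1:1 split is drawn from
    ``config.seed`` and the test part is ignored here.  Returns the selected
    parameters, the fold trace, and a context dict (vocab, l_max, t_max)
    needed to run the model on new documents.
    """
    if train_idx is None or val_idx is None:
        train_idx, val_idx, _ = make_split(corpus, seed=config.seed)
    train_docs = [corpus[i] for i in train_idx]
    val_docs = [corpus[i] for i in val_idx]
    if not train_docs or not val_docs:
        raise SplitError("train and validation sets must be non-empty")

    if vocab is None:
        vocab = textprep.build_vocab(train_docs + val_docs,
                                     min_count=config.min_count)
    l_pct, t_pct = textprep.percentile_limits(train_docs,
                                              config.length_percentile)
    l_max = config.l_max or l_pct
    t_max = config.t_max or t_pct
    logger.info("train: %d docs, val %d, vocab %d, L_max %d, T_max %d",
                len(train_docs), len(val_docs), len(vocab), l_max, t_max)

    params = init_params(config, vocab, embeddings=embeddings)
    opt = Adam(params, lr=config.learning_rate, grad_clip=config.grad_clip)
    rng = np.random.default_rng(config.seed + 1)

    best_params = params.copy()
    best_acc = -1.0
    best_epoch = 0
    trace: list[float] = []
    order = np.arange(len(train_docs))
    for epoch in range(1, config.epochs + 1):
        rng.shuffle(order)
        for start in range(0, len(order), config.batch_size):
            chunk = [train_docs[i] for i in order[start:start + config.batch_size]]
            batch = _trim_batch(
                textprep.encode_batch(chunk, vocab, l_max, t_max))
            loss, grads, _ = han_core.loss_and_grads(
                batch, params, dropout=config.dropout, training=True,
                rng=rng, ablation=config.ablation)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch "
                    f"{start // config.batch_size}")
            opt.step(params, grads)
        val_pred, _, _ = predict(params, val_docs, vocab, l_max, t_max,
                                 ablation=config.ablation)
        acc = float(np.mean([p == d.label for p, d in zip(val_pred, val_docs)]))
        trace.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_epoch = epoch
            best_params = params.copy()

    result = FoldResult(fold_index=0, best_epoch=best_epoch, val_trace=trace)
    context = {"vocab": vocab, "l_max": l_max, "t_max": t_max,
               "config": config}
    return best_params, result, context


def cross_validate(corpus: Sequence[CleanTranscript], config: TrainConfig,
                   k: int = 5,
                   ) -> tuple[list[FoldResult], MetricReport, MetricReport]:
    """Stratified k-fold cross-validation.

    Each fold trains on the other k-1 folds (with a stratified
    ``config.val_fraction`` validation subset carved out for epoch
    selection) and is evaluated on the held-out fold.  Returns per-fold
    results, the unweighted mean of fold metrics, and the pooled-confusion
    metrics.
    """
    folds = stratified_kfold(corpus, k, seed=config.seed)
    results: list[FoldResult] = []
    for f, test_idx in enumerate(folds):
        rest = [i for g, fold in enumerate(folds) if g != f for i in fold]
        tr_idx, va_idx = _carve_validation(corpus, rest, config.val_fraction,
                                           seed=config.seed + 1000 + f)
        params, fold_res, ctx = train(corpus, config, train_idx=tr_idx,
                                      val_idx=va_idx)
        test_docs = [corpus[i] for i in test_idx]
        preds, _, records = predict(params, test_docs, ctx["vocab"],
                                    ctx["l_max"], ctx["t_max"],
                                    ablation=config.ablation)
        fold_res.fold_index = f
        fold_res.metrics = evaluate(preds, [d.label for d in test_docs])
        fold_res.attention = records
        fold_res.predictions = preds
        fold_res.test_doc_ids = [d.doc_id for d in test_docs]
        results.append(fold_res)
        logger.info("fold %d: best epoch %d, test accuracy %.4f",
                    f, fold_res.best_epoch, fold_res.metrics.accuracy)
    aggregate = mean_report([r.metrics for r in results])
    pooled = pooled_report([r.metrics for r in results])
    return results, aggregate, pooled
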