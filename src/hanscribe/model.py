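"""Model/Results surface over the training machinery.

:class:`HanModel` is constructed from a labeled corpus (a list of
:class:`~hanscribe.transcripts.CleanTranscript`, a dataframe, or a JSON
Lines file) plus a :class:`~hanscribe.training.TrainConfig`.  ``fit()``
trains under the fixed 8:1:1 protocol and returns a :class:`HanResults`
carrying the selected parameters, validation trace, held-out test metrics
and attention records; ``fit_cv()`` runs stratified k-fold
cross-validation.  Both results objects print a ``summary()`` table and
can score and visualize new documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import attention_viz, textprep, training
from .errors import InputError
from .evaluation import MetricReport, evaluate
from .han_core import AttentionRecord, HanParams
from .training import FoldResult, TrainConfig
from .transcripts import CleanTranscript, load_corpus, normalize_label


class HanModel:
    """Hierarchical attention classifier for AD-vs-control transcripts."""

    def __init__(self, corpus: Sequence[CleanTranscript],
                 config: Optional[TrainConfig] = None):
        if not corpus:
            raise InputError("HanModel requires a non-empty corpus")
        if any(d.label is None for d in corpus):
            raise InputError("every document must carry a label")
        self.corpus = list(corpus)
        self.config = config or TrainConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, text_col: str = "text",
                       label_col: str = "label", id_col: Optional[str] = None,
                       config: Optional[TrainConfig] = None) -> "HanModel":
        """Build from a dataframe of raw text documents."""
        docs = []
        for i, row in df.reset_index(drop=True).iterrows():
            sentences = [textprep.tokenize(s)
                         for s in textprep.split_sentences(str(row[text_col]))]
            sentences = [s for s in sentences if s]
            docs.append(CleanTranscript(
                doc_id=str(row[id_col]) if id_col else f"doc-{i:05d}",
                sentences=sentences,
                label=normalize_label(row[label_col]),
            ))
        return cls(docs, config=config)

    @classmethod
    def from_jsonl(cls, path, config: Optional[TrainConfig] = None) -> "HanModel":
        return cls(load_corpus(path), config=config)

    def fit(self, seed: Optional[int] = None,
            embeddings=None) -> "HanResults":
        """Train on a stratified 8:1:1 split; evaluate on the test part."""
        config = self.config if seed is None else \
            training.replace(self.config, seed=seed)
        tr, va, te = training.make_split(self.corpus, seed=config.seed)
        params, fold, ctx = training.train(
            self.corpus, config, train_idx=tr, val_idx=va,
            embeddings=embeddings)
        test_docs = [self.corpus[i] for i in te]
        preds, probs, records = training.predict(
            params, test_docs, ctx["vocab"], ctx["l_max"], ctx["t_max"],
            ablation=config.ablation)
        fold.metrics = evaluate(preds, [d.label for d in test_docs])
        fold.attention = records
        fold.predictions = preds
        fold.test_doc_ids = [d.doc_id for d in test_docs]
        return HanResults(model=self, params=params, context=ctx,
                          fold=fold, protocol="fixed-split 8:1:1")

    def fit_cv(self, k: int = 5, seed: Optional[int] = None) -> "CrossValResults":
        """Stratified k-fold cross-validation at the configured settings."""
        config = self.config if seed is None else \
            training.replace(self.config, seed=seed)
        folds, aggregate, pooled = training.cross_validate(self.corpus,
                                                           config, k=k)
        return CrossValResults(model=self, folds=folds, aggregate=aggregate,
                               pooled=pooled, k=k, config=config)


@dataclass
class HanResults:
    """Fitted parameters, diagnostics, and scoring for new documents."""

    model: HanModel
    params: HanParams
    context: dict
    fold: FoldResult
    protocol: str

    @property
    def metrics(self) -> MetricReport:
        return self.fold.metrics

    def predict(self, docs: Sequence[CleanTranscript]
                ) -> tuple[list[str], np.ndarray, list[AttentionRecord]]:
        return training.predict(
            self.params, docs, self.context["vocab"],
            self.context["l_max"], self.context["t_max"],
            ablation=self.context["config"].ablation)

    def attention_report(self, docs: Sequence[CleanTranscript], out,
                         lexicons=None) -> str:
        """Render the attention heatmap report for the given documents."""
        preds, _, records = self.predict(docs)
        viz = [attention_viz.make_viz_document(d, r, predicted=p)
               for d, r, p in zip(docs, records, preds)]
        return attention_viz.render_html(viz, out, lexicons=lexicons)

    def save(self, path) -> None:
        cfg = self.context["config"]
        self.params.save(path, header={
            "config": cfg.to_dict(),
            "l_max": self.context["l_max"],
            "t_max": self.context["t_max"],
            "best_epoch": self.fold.best_epoch,
            "vocab_tokens": self.context["vocab"].index_to_token,
        })

    def summary(self) -> str:
        cfg = self.context["config"]
        lines = [
            "Hierarchical attention network — fit summary",
            "=" * 46,
            f"protocol        {self.protocol}",
            f"documents       {len(self.model.corpus)}",
            f"vocabulary      {len(self.context['vocab'])}",
            f"L_max / T_max   {self.context['l_max']} / {self.context['t_max']}",
            f"GRU units       {cfg.gru_units}   attention dim {cfg.attn_dim}",
            f"epochs          {cfg.epochs}   best epoch {self.fold.best_epoch}",
            f"dropout         {cfg.dropout}   lr {cfg.learning_rate}",
            f"ablation        {cfg.ablation}",
            "validation accuracy by epoch: "
            + " ".join(f"{a:.3f}" for a in self.fold.val_trace),
            "-" * 46,
            "held-out test metrics:",
            self.metrics.as_text(),
        ]
        return "\n".join(lines)


@dataclass
class CrossValResults:
    """Per-fold and aggregate cross-validation results."""

    model: HanModel
    folds: list[FoldResult]
    aggregate: MetricReport
    pooled: MetricReport
    k: int
    config: TrainConfig

    def summary(self) -> str:
        lines = [
            f"Hierarchical attention network — {self.k}-fold cross-validation",
            "=" * 56,
            f"documents  {len(self.model.corpus)}   ablation {self.config.ablation}",
            f"{'fold':>4} {'best epoch':>10} {'accuracy':>9} {'f1':>7}",
        ]
        for r in self.folds:
            acc = f"{r.metrics.accuracy:.4f}" if r.metrics.accuracy is not None else "--"
            f1 = f"{r.metrics.f1:.4f}" if r.metrics.f1 is not None else "--"
            lines.append(f"{r.fold_index:>4} {r.best_epoch:>10} {acc:>9} {f1:>7}")
        lines += [
            "-" * 56,
            "mean of fold metrics:",
            self.aggregate.as_text(),
            "pooled confusion:",
            self.pooled.as_text(),
        ]
        return "\n".join(lines)
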