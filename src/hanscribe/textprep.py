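"""Sentence splitting, tokenization, vocabulary and batch encoding.

The default splitter/tokenizer is rule-based so that the package has no
external runtime dependency; any external tokenizer can be plugged in by
passing callables with the same signatures to the corpus readers.

Encoding pads documents into a dense ``[documents x sentences x words]``
integer block with validity masks at both levels, the shape the
hierarchical encoder consumes.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptyDocumentError,
    FormatError,
    InputError,
)
from .transcripts import CleanTranscript

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_SENTENCE_BOUNDARY = re.compile(r"(?<=[.?!])\s+")
_TOKEN_RE = re.compile(r"\w+(?:'\w+)?|[^\w\s]")


def split_sentences(text: str) -> list[str]:
    """Split text on sentence-final ``.``, ``?``, ``!`` followed by whitespace.

    Deliberately simple: picture-description transcripts contain almost no
    abbreviations, so terminal punctuation is a reliable boundary.
    """
    if not re.search(r"\w", text or ""):
        raise EmptyDocumentError("text contains no word characters")
    pieces = [p.strip() for p in _SENTENCE_BOUNDARY.split(text.strip())]
    return [p for p in pieces if p]


def tokenize(sentence: str) -> list[str]:
    """Lowercase, NFC-normalize, and split into word/punctuation tokens."""
    norm = unicodedata.normalize("NFC", sentence).lower()
    return _TOKEN_RE.findall(norm)


@dataclass
class Vocabulary:
    """Deterministic token<->index bijection with PAD=0 and UNK=1.

    Tokens are ordered by descending corpus frequency, then lexicographically,
    so the same corpus always yields byte-identical indexing.
    """

    token_to_index: dict[str, int]
    index_to_token: list[str]
    min_count: int = 1
    pad_index: int = 0
    unk_index: int = 1

    def __len__(self) -> int:
        return len(self.index_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def encode_token(self, token: str) -> int:
        return self.token_to_index.get(token, self.unk_index)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"min_count": self.min_count, "tokens": self.index_to_token},
                ensure_ascii=False,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        tokens = d["tokens"]
        return cls(
            token_to_index={t: i for i, t in enumerate(tokens)},
            index_to_token=list(tokens),
            min_count=int(d.get("min_count", 1)),
        )


def build_vocab(corpus: Sequence[CleanTranscript], min_count: int = 1) -> Vocabulary:
    """Fit a vocabulary on a corpus.

    Tokens occurring fewer than ``min_count`` times map to UNK at encode
    time.  PAD and UNK are always present at indices 0 and 1.
    """
    if not corpus:
        raise InputError("cannot build a vocabulary from an empty corpus")
    if min_count < 1:
        raise ConfigError(f"min_count must be >= 1, got {min_count}")
    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(doc.tokens())
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    index_to_token = [PAD_TOKEN, UNK_TOKEN] + kept
    return Vocabulary(
        token_to_index={t: i for i, t in enumerate(index_to_token)},
        index_to_token=index_to_token,
        min_count=min_count,
    )


@dataclass
class EmbeddingMatrix:
    """Dense token-embedding table; row 0 (PAD) is pinned to zero."""

    weights: np.ndarray  # (V, d)
    dim: int
    trainable: bool = True

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[1] != self.dim:
            raise ConfigError(
                f"embedding weights shape {self.weights.shape} inconsistent "
                f"with dim {self.dim}"
            )
        self.weights[0, :] = 0.0


def random_embeddings(
    vocab: Vocabulary,
    dim: int = 100,
    seed: int = 0,
    std: float = 0.1,
    trainable: bool = True,
    dtype=np.float64,
) -> EmbeddingMatrix:
    """Initialize all rows from normal(0, std); PAD row zeroed."""
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, std, size=(len(vocab), dim)).astype(dtype)
    return EmbeddingMatrix(weights=W, dim=dim, trainable=trainable)


def load_embeddings(
    path,
    vocab: Vocabulary,
    dim: int = 100,
    seed: int = 0,
    std: float = 0.1,
    trainable: bool = True,
    dtype=np.float64,
) -> EmbeddingMatrix:
    """Load GloVe-text-format vectors for a vocabulary.

    Each line is ``token v1 ... v_dim``.  Tokens absent from the file are
    drawn from normal(0, std) with the given seed so runs are reproducible;
    the PAD row is forced to zero.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"embedding file not found: {path}")
    emb = random_embeddings(vocab, dim=dim, seed=seed, std=std,
                            trainable=trainable, dtype=dtype)
    found = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, values = parts[0], parts[1:]
            if token not in vocab:
                continue
            if len(values) != dim:
                raise FormatError(
                    f"{path}:{lineno}: expected {dim} values for "
                    f"{token!r}, found {len(values)}"
                )
            emb.weights[vocab.token_to_index[token]] = np.asarray(
                values, dtype=dtype
            )
            found += 1
    emb.weights[vocab.pad_index, :] = 0.0
    emb.loaded_tokens = found  # type: ignore[attr-defined]
    return emb


@dataclass
class EncodedBatch:
    """Padded token-index block with validity masks at both levels."""

    token_ids: np.ndarray      # (B, L, T) int
    word_mask: np.ndarray      # (B, L, T) float {0,1}
    sentence_mask: np.ndarray  # (B, L) float {0,1}
    labels: np.ndarray         # (B,) int; -1 for unlabeled
    doc_ids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return self.token_ids.shape[0]

    def validate(self) -> None:
        if not np.all(self.token_ids[self.word_mask == 0] == 0):
            raise InputError("token_ids must equal pad_index where word_mask is 0")
        derived = (self.word_mask.sum(axis=2) > 0).astype(self.sentence_mask.dtype)
        if not np.array_equal(derived, self.sentence_mask):
            raise InputError("sentence_mask inconsistent with word_mask")


def percentile_limits(
    docs: Sequence[CleanTranscript], pct: float = 95.0
) -> tuple[int, int]:
    """(L_max, T_max): the pct-th percentile of sentence and word counts."""
    n_sent = [d.n_sentences for d in docs]
    n_word = [len(s) for d in docs for s in d.sentences]
    l_max = int(np.ceil(np.percentile(n_sent, pct)))
    t_max = int(np.ceil(np.percentile(n_word, pct)))
    return max(l_max, 1), max(t_max, 1)


def encode_batch(
    docs: Sequence[CleanTranscript],
    vocab: Vocabulary,
    l_max: int,
    t_max: int,
) -> EncodedBatch:
    """Truncate each document to its first ``l_max`` sentences and each
    sentence to its first ``t_max`` tokens, then pad and mask."""
    if l_max < 1 or t_max < 1:
        raise ConfigError("l_max and t_max must be >= 1")
    if not docs:
        raise InputError("encode_batch requires at least one document")
    B = len(docs)
    ids = np.zeros((B, l_max, t_max), dtype=np.int64)
    wmask = np.zeros((B, l_max, t_max), dtype=np.float64)
    smask = np.zeros((B, l_max), dtype=np.float64)
    labels = np.full(B, -1, dtype=np.int64)
    for b, doc in enumerate(docs):
        if doc.n_sentences == 0:
            raise InputError(f"document {doc.doc_id!r} is empty")
        for i, sent in enumerate(doc.sentences[:l_max]):
            toks = sent[:t_max]
            ids[b, i, : len(toks)] = [vocab.encode_token(t) for t in toks]
            wmask[b, i, : len(toks)] = 1.0
            smask[b, i] = 1.0
        labels[b] = doc.label_index
    return EncodedBatch(
        token_ids=ids,
        word_mask=wmask,
        sentence_mask=smask,
        labels=labels,
        doc_ids=[d.doc_id for d in docs],
    )


def unk_rate(docs: Sequence[CleanTranscript], vocab: Vocabulary) -> float:
    """Fraction of corpus tokens that map to UNK under the vocabulary."""
    total = 0
    unk = 0
    for doc in docs:
        for tok in doc.tokens():
            total += 1
            if vocab.encode_token(tok) == vocab.unk_index:
                unk += 1
    return unk / total if total else 0.0
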