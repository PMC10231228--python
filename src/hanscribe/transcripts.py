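"""Core transcript container shared by the I/O, preprocessing and synthesis layers.

A transcript is an ordered list of sentences, each an ordered list of
lowercase tokens, optionally carrying a binary diagnosis label.  The two
classes are ``CTRL`` (cognitively healthy control) and ``AD`` (Alzheimer's
disease); ``AD`` is the positive class throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import EmptyDocumentError, InputError

#: Class-index convention used everywhere: index 0 = CTRL, index 1 = AD.
LABELS = ("CTRL", "AD")
LABEL_TO_INDEX = {"CTRL": 0, "AD": 1}

#: Accepted spellings in manifests and label columns (case-insensitive).
_LABEL_ALIASES = {
    "ad": "AD",
    "dementia": "AD",
    "ctrl": "CTRL",
    "nc": "CTRL",
    "control": "CTRL",
    "hc": "CTRL",
}

#: CHAT annotation characters that must never survive in a clean token.
FORBIDDEN_CHARS = set("[]<>&@%*")


def normalize_label(raw: str) -> str:
    """Map a free-form label string to ``"AD"`` or ``"CTRL"``."""
    key = str(raw).strip().lower()
    if key not in _LABEL_ALIASES:
        raise InputError(f"unknown label {raw!r}; expected one of AD/CTRL/NC")
    return _LABEL_ALIASES[key]


@dataclass
class CleanTranscript:
    """One document reduced to pure participant text.

    Attributes
    ----------
    doc_id : str
        Stable document identifier.
    sentences : list of list of str
        Ordered sentences, each a non-empty ordered list of lowercase tokens.
    label : str or None
        ``"AD"``, ``"CTRL"`` or ``None`` for unlabeled documents.
    patient_id : str or None
        Optional grouping key so that multiple visits of one patient can be
        kept on the same side of a data split.
    source_path : str or None
        Provenance of the raw document, if read from disk.
    """

    doc_id: str
    sentences: list[list[str]]
    label: Optional[str] = None
    patient_id: Optional[str] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sentences:
            raise EmptyDocumentError(f"document {self.doc_id!r} has no sentences")
        for sent in self.sentences:
            if not sent:
                raise EmptyDocumentError(
                    f"document {self.doc_id!r} contains an empty sentence"
                )
            for tok in sent:
                bad = FORBIDDEN_CHARS.intersection(tok)
                if bad:
                    raise InputError(
                        f"token {tok!r} in document {self.doc_id!r} contains "
                        f"annotation characters {sorted(bad)}"
                    )
        if self.label is not None and self.label not in LABELS:
            raise InputError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def label_index(self) -> int:
        if self.label is None:
            return -1
        return LABEL_TO_INDEX[self.label]

    def tokens(self) -> Iterable[str]:
        for sent in self.sentences:
            yield from sent

    def to_dict(self) -> dict:
        d = {"doc_id": self.doc_id, "sentences": self.sentences}
        if self.label is not None:
            d["label"] = self.label
        if self.patient_id is not None:
            d["patient_id"] = self.patient_id
        if self.source_path is not None:
            d["source_path"] = self.source_path
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CleanTranscript":
        return cls(
            doc_id=d["doc_id"],
            sentences=[list(s) for s in d["sentences"]],
            label=d.get("label"),
            patient_id=d.get("patient_id"),
            source_path=d.get("source_path"),
        )


def save_corpus(corpus: Iterable[CleanTranscript], path) -> None:
    """Write a corpus as JSON Lines, one transcript per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc.to_dict(), ensure_ascii=False) + "\n")


def load_corpus(path) -> list[CleanTranscript]:
    """Read a JSON Lines corpus written by :func:`save_corpus`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"corpus file not found: {path}")
    docs = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(CleanTranscript.from_dict(json.loads(line)))
    return docs
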