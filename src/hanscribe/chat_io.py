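"""Reading CHAT-format (.cha) and plain-text transcripts.

CHAT is the TalkBank transcription standard: speaker tiers (``*PAR:``,
``*INV:``), dependent tiers (``%mor:``, ``%gra:``), header lines (``@Begin``)
and a rich inventory of inline dysfluency/retracing codes.  This module
reduces such files to pure participant text: only the chosen speaker's
utterances are kept, every dependent tier and inline code is dropped, and
the surviving words are lowercased and tokenized on whitespace.

The exact code-removal rules are collected in :data:`STRIP_RULES` as a
single editable table so that other CHAT dialects can be matched by editing
one place.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import EmptyDocumentError, FormatError, InputError
from .transcripts import FORBIDDEN_CHARS, CleanTranscript, normalize_label

#: Ordered (pattern, replacement) regex table applied to each utterance.
#: Editing this table is the supported way to match other CHAT dialects.
STRIP_RULES: list[tuple[str, str]] = [
    (r"\[[^\]]*\]", " "),        # bracketed codes: [//] [/] [: text] [* pos] [+ exc] ...
    (r"&=?\S+", " "),            # &=laughs &-um &uh : non-word events / phonology
    (r"@\S*", ""),               # word@o, word@u form markers: keep the stem
    (r"\(\.{1,3}\)", " "),       # pause symbols (.) (..) (...)
    (r"\+\S*", " "),             # special utterance terminators +... +//. etc.
    (r"[<>]", " "),              # angle-bracket scope markers: keep the words
    (r"[()]", ""),               # shortening parentheses: (be)cause -> because
    (r"“|”|‘|’", ""),  # smart quotes
]

_COMPILED_RULES = [(re.compile(pat), rep) for pat, rep in STRIP_RULES]

_TIER_RE = re.compile(r"^([*%][A-Za-z0-9]+):\s?(.*)$")


@dataclass
class RawChatDocument:
    """A parsed .cha file: ordered tiers, nothing interpreted yet."""

    doc_id: str
    tiers: list[tuple[str, str]]
    source_path: str = ""

    def speaker_tiers(self, speaker: str) -> list[str]:
        """Contents of every ``*<speaker>:`` tier, in file order."""
        want = f"*{speaker.upper()}"
        return [content for label, content in self.tiers if label.upper() == want]


def read_chat_file(path, speaker: str = "PAR") -> RawChatDocument:
    """Parse a CHAT file into its tiers.

    Continuation lines (leading tab) are joined to their owning tier.
    Header lines (``@Begin``, ``@ID`` ...) are ignored.  The requested
    speaker is not filtered here — :func:`strip_annotations` does that — but
    its absence is already an error so that problems surface at read time.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"CHAT file not found: {path}")
    text = path.read_text(encoding="utf-8")
    tiers: list[tuple[str, str]] = []
    for raw_line in text.splitlines():
        if not raw_line.strip():
            continue
        if raw_line.startswith(("\t", " ")) and tiers:
            label, content = tiers[-1]
            tiers[-1] = (label, (content + " " + raw_line.strip()).strip())
            continue
        if raw_line.startswith("@"):
            continue
        m = _TIER_RE.match(raw_line)
        if m:
            tiers.append((m.group(1), m.group(2).strip()))
        # anything else (stray text without a tier marker) is ignored
    doc = RawChatDocument(doc_id=path.stem, tiers=tiers, source_path=str(path))
    if not tiers:
        raise EmptyDocumentError(f"{path}: no CHAT tiers found")
    if not doc.speaker_tiers(speaker):
        raise EmptyDocumentError(f"{path}: no tier for speaker {speaker!r}")
    return doc


def _clean_utterance(utterance: str) -> list[str]:
    """Apply the strip-rule table to one utterance and tokenize."""
    text = unicodedata.normalize("NFC", utterance)
    for pattern, replacement in _COMPILED_RULES:
        text = pattern.sub(replacement, text)
    tokens = []
    for tok in text.lower().split():
        if FORBIDDEN_CHARS.intersection(tok):
            continue  # defensive: drop anything a rule missed
        tokens.append(tok)
    return tokens


def strip_annotations(
    doc: RawChatDocument,
    speaker: str = "PAR",
    label: Optional[str] = None,
) -> CleanTranscript:
    """Reduce a parsed CHAT document to pure text for one speaker.

    Dependent tiers (``%mor``, ``%gra`` ...) and other speakers are dropped;
    each surviving utterance becomes one sentence of lowercase tokens with
    all inline codes removed per :data:`STRIP_RULES`.
    """
    sentences = []
    for utterance in doc.speaker_tiers(speaker):
        tokens = _clean_utterance(utterance)
        if tokens:
            sentences.append(tokens)
    if not sentences:
        raise EmptyDocumentError(
            f"document {doc.doc_id!r}: no text left for speaker {speaker!r} "
            "after annotation stripping"
        )
    return CleanTranscript(
        doc_id=doc.doc_id,
        sentences=sentences,
        label=label,
        source_path=doc.source_path,
    )


def read_chat_corpus(paths, speaker: str = "PAR", labels: Optional[dict] = None):
    """Read several .cha files; ``labels`` maps doc_id -> label string."""
    corpus = []
    for p in paths:
        raw = read_chat_file(p, speaker=speaker)
        lab = None
        if labels is not None and raw.doc_id in labels:
            lab = normalize_label(labels[raw.doc_id])
        corpus.append(strip_annotations(raw, speaker=speaker, label=lab))
    return corpus


def write_chat_file(transcript: CleanTranscript, path, speaker: str = "PAR") -> None:
    """Emit a minimal synthetic .cha file (one speaker tier per sentence)."""
    lines = ["@Begin", f"@Participants:\t{speaker} Participant"]
    for sent in transcript.sentences:
        lines.append(f"*{speaker}:\t{' '.join(sent)}")
    lines.append("@End")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_plaintext_corpus(directory, manifest) -> list[CleanTranscript]:
    """Read plain-text documents listed in a CSV manifest.

    The manifest must have columns ``doc_id,filename,label`` and may carry an
    optional ``patient_id`` column.  Each file is sentence-split and
    tokenized with the default :mod:`hanscribe.textprep` pipeline; labels are
    case-folded (AD -> positive class).
    """
    from . import textprep  # local import; textprep depends on transcripts only

    directory = Path(directory)
    manifest = Path(manifest)
    if not manifest.exists():
        raise InputError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest, dtype=str)
    required = {"doc_id", "filename", "label"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{manifest}: manifest missing columns {sorted(missing)}")
    corpus = []
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        fpath = directory / row.filename
        if not fpath.exists():
            raise InputError(
                f"manifest row {row_number}: file {row.filename!r} not found "
                f"under {directory}"
            )
        text = fpath.read_text(encoding="utf-8")
        sentences = [
            textprep.tokenize(s) for s in textprep.split_sentences(text)
        ]
        sentences = [s for s in sentences if s]
        if not sentences:
            raise EmptyDocumentError(
                f"manifest row {row_number}: {row.filename!r} has no text"
            )
        corpus.append(
            CleanTranscript(
                doc_id=str(row.doc_id),
                sentences=sentences,
                label=normalize_label(row.label),
                patient_id=str(row.patient_id)
                if "patient_id" in table.columns and pd.notna(row.patient_id)
                else None,
                source_path=str(fpath),
            )
        )
    return corpus
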