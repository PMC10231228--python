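"""Hierarchical attention normalization and HTML transcript heatmaps.

The report shows one block per document: each sentence on its own line
with a red left bar whose opacity scales with the sentence weight, and
each token shaded green with opacity proportional to its hierarchically
normalized weight (sentence weight x word weight), rescaled by the
per-document maximum so short documents stay readable.  Rendering is a
pure function of its inputs: identical documents yield byte-identical
HTML.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .han_core import AttentionRecord
from .synthgen import FILLER_WORDS, PRONOUN_WORDS, SEED_WORDS
from .transcripts import CleanTranscript

#: Lexicons underlined in reports and used for attention-mass accounting.
DEFAULT_LEXICONS: dict[str, tuple[str, ...]] = {
    "seed": SEED_WORDS,
    "filler": FILLER_WORDS,
    "pronoun": PRONOUN_WORDS,
}


@dataclass
class VizSentence:
    tokens: list[str]
    token_weights: np.ndarray  # normalized (hierarchical) weights
    sentence_weight: float


@dataclass
class VizDocument:
    doc_id: str
    sentences: list[VizSentence]
    predicted_class: Optional[str] = None
    true_class: Optional[str] = None

    def total_weight(self) -> float:
        return float(sum(s.token_weights.sum() for s in self.sentences))

    def lexicon_mass(self, lexicon: Sequence[str]) -> float:
        """Total normalized attention mass on tokens from a lexicon."""
        lex = set(lexicon)
        mass = 0.0
        for s in self.sentences:
            for tok, w in zip(s.tokens, s.token_weights):
                if tok in lex:
                    mass += float(w)
        return mass


def normalize_attention(record: AttentionRecord) -> list[np.ndarray]:
    """Per-sentence arrays of hierarchical weights m_i * m_it.

    Validates the simplex invariants first; the result sums to 1 over the
    whole document.
    """
    record.validate()
    return record.normalized_word_weights


def make_viz_document(doc: CleanTranscript, record: AttentionRecord,
                      predicted: Optional[str] = None) -> VizDocument:
    """Pair a transcript with its attention record.

    The record may cover fewer sentences/tokens than the transcript when
    the encoder truncated the document; surplus text gets zero weight.
    """
    norm = normalize_attention(record)
    sentences = []
    for i, sent in enumerate(doc.sentences):
        if i < len(norm):
            w = np.zeros(len(sent))
            n = min(len(sent), len(norm[i]))
            w[:n] = norm[i][:n]
            sw = float(record.sentence_weights[i])
        else:
            w = np.zeros(len(sent))
            sw = 0.0
        sentences.append(VizSentence(tokens=list(sent), token_weights=w,
                                     sentence_weight=sw))
    return VizDocument(doc_id=doc.doc_id, sentences=sentences,
                       predicted_class=predicted, true_class=doc.label)


_CSS = """
body { font-family: Georgia, serif; margin: 2em auto; max-width: 50em; }
.doc { margin-bottom: 2em; }
.doc h2 { font-size: 1em; font-family: monospace; }
.sent { padding: 0.15em 0.4em; margin: 0.1em 0; border-left: 0.5em solid; }
.tok { padding: 0 0.12em; border-radius: 2px; }
.lex { text-decoration: underline; }
.meta { color: #555; font-size: 0.85em; }
table.mass { border-collapse: collapse; font-size: 0.85em; }
table.mass td, table.mass th { border: 1px solid #ccc; padding: 0.2em 0.6em; }
"""

_HEADER_NOTE = (
    "Green shading: hierarchically normalized word weight (sentence weight "
    "x word weight), rescaled by each document's maximum. Red left bar: "
    "sentence weight, rescaled by each document's maximum. Underline: "
    "lexicon token."
)


def _render_document(doc: VizDocument,
                     lexicons: dict[str, Sequence[str]]) -> list[str]:
    all_w = np.concatenate([s.token_weights for s in doc.sentences]) \
        if doc.sentences else np.zeros(1)
    w_max = float(all_w.max()) if all_w.size else 0.0
    s_max = max((s.sentence_weight for s in doc.sentences), default=0.0)
    lex_union = {tok for lex in lexicons.values() for tok in lex}

    parts = [f'<div class="doc" id="{html.escape(doc.doc_id)}">']
    title = html.escape(doc.doc_id)
    meta = []
    if doc.predicted_class is not None:
        meta.append(f"predicted {doc.predicted_class}")
    if doc.true_class is not None:
        meta.append(f"true {doc.true_class}")
    parts.append(f"<h2>{title}"
                 + (f' <span class="meta">({", ".join(meta)})</span>' if meta else "")
                 + "</h2>")
    for s in doc.sentences:
        bar = s.sentence_weight / s_max if s_max > 0 else 0.0
        parts.append(
            f'<div class="sent" style="border-left-color:'
            f'rgba(200,30,30,{bar:.6f})">'
        )
        spans = []
        for tok, w in zip(s.tokens, s.token_weights):
            alpha = w / w_max if w_max > 0 else 0.0
            cls = "tok lex" if tok in lex_union else "tok"
            style = f"background:rgba(30,160,30,{alpha:.6f})" if alpha > 0 else ""
            spans.append(f'<span class="{cls}" style="{style}">'
                         f"{html.escape(tok)}</span>")
        parts.append(" ".join(spans))
        parts.append("</div>")
    if lexicons:
        rows = "".join(
            f"<tr><td>{html.escape(name)}</td>"
            f"<td>{doc.lexicon_mass(lex):.6f}</td></tr>"
            for name, lex in sorted(lexicons.items())
        )
        parts.append('<table class="mass"><tr><th>lexicon</th>'
                     "<th>attention mass</th></tr>" + rows + "</table>")
    parts.append("</div>")
    return parts


def render_html(docs: Sequence[VizDocument], out,
                lexicons: Optional[dict[str, Sequence[str]]] = None,
                title: str = "Attention report") -> str:
    """Write a self-contained HTML report plus a JSON sidecar of weights.

    Returns the HTML string (also written to ``out``); the sidecar goes to
    ``out`` with ``.json`` appended.
    """
    if lexicons is None:
        lexicons = DEFAULT_LEXICONS
    parts = [
        "<!DOCTYPE html>",
        '<html><head><meta charset="utf-8">',
        f"<title>{html.escape(title)}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>{html.escape(title)}</h1>",
        f'<p class="meta">{html.escape(_HEADER_NOTE)}</p>',
    ]
    for doc in docs:
        parts.extend(_render_document(doc, lexicons))
    parts.append("</body></html>")
    text = "\n".join(parts) + "\n"

    out = Path(out)
    try:
        out.write_text(text, encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write report to {out}: {exc}") from exc

    sidecar = {
        "documents": [
            {
                "doc_id": d.doc_id,
                "predicted_class": d.predicted_class,
                "true_class": d.true_class,
                "sentence_weights": [s.sentence_weight for s in d.sentences],
                "normalized_word_weights": [
                    [float(w) for w in s.token_weights] for s in d.sentences
                ],
                "lexicon_mass": {name: d.lexicon_mass(lex)
                                 for name, lex in sorted(lexicons.items())},
            }
            for d in docs
        ]
    }
    Path(str(out) + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True), encoding="utf-8")
    return text
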