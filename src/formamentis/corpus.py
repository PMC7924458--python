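"""Short-text cleaning, admission filtering and sentence splitting.

Mirrors the preprocessing used for tweet corpora: hashtag and mention
characters are stripped (the token text is kept), URLs and pictographic
codepoints are discarded, and documents shorter than three words are not
admitted to the analysis.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "Document",
    "clean_text",
    "admit_document",
    "split_sentences",
    "load_documents",
    "prepare_documents",
]

_URL_RE = re.compile(r"""(?:https?://|www\.)\S+""", re.IGNORECASE)

# Pictographic / emoji codepoint blocks (discarded wholesale).
_EMOJI_RE = re.compile(
    "["
    "\U0001f000-\U0001faff"  # symbols, pictographs, emoticons, transport...
    "\U00002600-\U000027bf"  # misc symbols + dingbats
    "\U0001f1e6-\U0001f1ff"  # regional indicators
    "\U00002190-\U000021ff"  # arrows
    "\U00002b00-\U00002bff"
    "︎️‍"     # variation selectors, ZWJ
    "]+"
)

_SENT_RE = re.compile(r"[.!?]+")


def clean_text(raw: str, strip_mentions: bool = True) -> str:
    """Strip URLs, emoji, and hashtag/mention markers; normalise spaces.

    The ``#``/``@`` characters are removed but the token text is kept
    ("#science" → "science"). Whether ``@`` is stripped is configurable
    (``strip_mentions``) since handle treatment is a corpus-level choice.
    """
    text = _URL_RE.sub(" ", raw)
    text = _EMOJI_RE.sub(" ", text)
    text = text.replace("#", " ")
    if strip_mentions:
        text = text.replace("@", " ")
    return " ".join(text.split())


def admit_document(cleaned: str, min_words: int = 3) -> bool:
    """True iff the cleaned text has at least ``min_words`` whitespace tokens."""
    return len(cleaned.split()) >= min_words


def split_sentences(cleaned: str) -> List[str]:
    """Split on terminal punctuation (., !, ?).

    This is the naive splitter: abbreviations like "Dr." produce an
    extra boundary. A parser backend with its own sentenciser may be
    used upstream instead; this function is the deterministic default.
    """
    parts = [p.strip() for p in _SENT_RE.split(cleaned)]
    sentences = [p for p in parts if p]
    return sentences if sentences else ([] if not cleaned.strip() else [cleaned.strip()])


@dataclass
class Document:
    """One short text: raw form, cleaned form, and its sentences."""

    id: str
    raw: str
    cleaned: str = ""
    sentences: List[str] = field(default_factory=list)

    @classmethod
    def from_raw(cls, id: str, raw: str, strip_mentions: bool = True) -> "Document":
        cleaned = clean_text(raw, strip_mentions=strip_mentions)
        return cls(id=id, raw=raw, cleaned=cleaned, sentences=split_sentences(cleaned))


def load_documents(path, text_column: str = "text") -> Iterator[Tuple[str, str]]:
    """Yield (id, raw_text) rows from a plain-text or CSV source.

    Plain text: one document per line, ids are 1-based line numbers.
    CSV (by ``.csv`` suffix): header required, columns ``id`` and
    ``text`` (text column name configurable).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or text_column not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must have a header with a {text_column!r} column")
            for i, row in enumerate(reader, start=1):
                yield str(row.get("id", i)), row[text_column]
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line.strip():
                    yield str(i), line


def prepare_documents(
    raw_docs: Iterable[Tuple[str, str]],
    min_words: int = 3,
    strip_mentions: bool = True,
) -> Tuple[List[Document], int]:
    """Clean and filter raw documents.

    Returns the admitted documents and the number discarded by the
    ``min_words`` filter.
    """
    admitted: List[Document] = []
    discarded = 0
    for doc_id, raw in raw_docs:
        doc = Document.from_raw(doc_id, raw, strip_mentions=strip_mentions)
        if admit_document(doc.cleaned, min_words=min_words):
            admitted.append(doc)
        else:
            discarded += 1
    return admitted, discarded
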