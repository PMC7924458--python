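"""Psycholinguistic resource loading and stem-level valence labelling.

Four resources drive a forma mentis analysis:

* **valence norms** — continuous positive/negative affect ratings of words
  from behavioural mega-studies (e.g. Warriner-style 1–9 ratings);
* **a word–emotion association lexicon** — which of Plutchik's eight basic
  emotions (anger, disgust, fear, trust, joy, sadness, surprise,
  anticipation) each word evokes;
* **synonym pairs** and **antonym pairs** (WordNet-style exports).

All files are two-column UTF-8 TSV; ``#`` starts a comment line. Loaders
do not ship the third-party datasets themselves — users supply exports.

Valence labelling follows the quartile convention: stems whose mean score
lies above the 75th percentile of the stem-score distribution are
*positive*, below the 25th percentile *negative*, and *neutral* in the
interquartile range. Scores are first averaged over all words sharing a
stemmed root, because network nodes are stems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

import numpy as np

from .stemming import Stemmer, stem as default_stem

logger = logging.getLogger(__name__)

__all__ = [
    "EMOTIONS",
    "ValenceNorms",
    "StemValenceTable",
    "ValenceLabelMap",
    "EmotionLexicon",
    "PairLexicon",
    "LexiconBundle",
    "LexiconParseError",
    "load_valence_norms",
    "load_emotion_lexicon",
    "load_pair_lexicon",
    "load_lexicons",
    "stem_aggregate_valence",
    "assign_valence_labels",
    "emotions_of",
]

#: Plutchik's eight basic emotions, the only tags an emotion lexicon may use.
EMOTIONS: Tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "trust",
    "joy",
    "sadness",
    "surprise",
    "anticipation",
)

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"
UNKNOWN = "unknown"


class LexiconParseError(ValueError):
    """Malformed lexicon row (wrong column count or non-numeric score)."""


@dataclass(frozen=True)
class ValenceNorms:
    """Word → continuous valence score, words lowercase and unique."""

    entries: Mapping[str, float]

    def __post_init__(self):
        for w, s in self.entries.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite valence score for {w!r}")


@dataclass(frozen=True)
class StemValenceTable:
    """Stem → mean valence over all norm words sharing that stem."""

    entries: Mapping[str, float]


@dataclass(frozen=True)
class ValenceLabelMap:
    """Stem → {positive, neutral, negative} by quartile position.

    ``positive`` iff score > q3 (strict), ``negative`` iff score < q1
    (strict); ties with the quartile values fall to ``neutral``.
    """

    labels: Mapping[str, str]
    q1: float
    q3: float

    def label(self, stem_: str) -> str:
        """Label of a stem, ``"unknown"`` if absent from the norms."""
        return self.labels.get(stem_, UNKNOWN)


class EmotionLexicon:
    """Word → subset of the eight basic emotions.

    Lookups fall back to the stemmed key when the surface form is absent:
    network nodes are stems while emotion lexicons index surface words,
    so a stem inherits the union of the emotions of its member words.
    """

    def __init__(self, entries: Mapping[str, Set[str]], stemmer: Optional[Stemmer] = None):
        bad = {e for ems in entries.values() for e in ems} - set(EMOTIONS)
        if bad:
            raise ValueError(f"unknown emotion tags: {sorted(bad)}")
        self.entries: Dict[str, FrozenSet[str]] = {
            w.lower(): frozenset(e) for w, e in entries.items()
        }
        self._stemmer = stemmer or default_stem
        self._by_stem: Dict[str, FrozenSet[str]] = {}
        for w, ems in self.entries.items():
            s = self._stemmer(w)
            self._by_stem[s] = self._by_stem.get(s, frozenset()) | ems

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def emotions_of(self, word: str) -> FrozenSet[str]:
        w = word.lower()
        if w in self.entries:
            return self.entries[w]
        return self._by_stem.get(self._stemmer(w), frozenset())

    def eligible_words(self) -> Tuple[str, ...]:
        """Words carrying at least one emotion, sorted (null-model pool)."""
        return tuple(sorted(w for w, e in self.entries.items() if e))


@dataclass(frozen=True)
class PairLexicon:
    """Symmetric, self-pair-free set of unordered word pairs."""

    pairs: FrozenSet[Tuple[str, str]]

    @classmethod
    def from_pairs(cls, raw: Iterable[Tuple[str, str]]) -> "PairLexicon":
        out = set()
        for a, b in raw:
            a, b = a.lower(), b.lower()
            if a != b:
                out.add((min(a, b), max(a, b)))
        return cls(frozenset(out))

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        a, b = pair[0].lower(), pair[1].lower()
        return (min(a, b), max(a, b)) in self.pairs

    def partners_of(self, word: str) -> FrozenSet[str]:
        w = word.lower()
        return frozenset(b if a == w else a for a, b in self.pairs if w in (a, b))


@dataclass(frozen=True)
class LexiconBundle:
    """All resources needed to build and profile a forma mentis network."""

    valence: ValenceNorms
    emotions: EmotionLexicon
    synonyms: PairLexicon
    antonyms: PairLexicon
    stemmer: Stemmer = field(default=default_stem)


def _iter_tsv_rows(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise LexiconParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            yield lineno, cols[0].strip(), cols[1].strip()


def load_valence_norms(path) -> ValenceNorms:
    path = Path(path)
    entries: Dict[str, float] = {}
    for lineno, word, score_s in _iter_tsv_rows(path):
        try:
            score = float(score_s)
        except ValueError:
            score = float("nan")
        if not np.isfinite(score):
            raise LexiconParseError(
                f"{path}: line {lineno}: non-numeric valence score {score_s!r}"
            )
        w = word.lower()
        if w in entries:
            logger.warning("%s: line %d: duplicate word %r, last value wins", path, lineno, w)
        entries[w] = score
    return ValenceNorms(entries)


def load_emotion_lexicon(path, stemmer: Optional[Stemmer] = None) -> EmotionLexicon:
    path = Path(path)
    entries: Dict[str, Set[str]] = {}
    for lineno, word, emotion in _iter_tsv_rows(path):
        emotion = emotion.lower()
        if emotion not in EMOTIONS:
            raise LexiconParseError(
                f"{path}: line {lineno}: unknown emotion {emotion!r}"
            )
        entries.setdefault(word.lower(), set()).add(emotion)
    return EmotionLexicon(entries, stemmer=stemmer)


def load_pair_lexicon(path) -> PairLexicon:
    path = Path(path)
    return PairLexicon.from_pairs(
        (a, b) for _, a, b in _iter_tsv_rows(path)
    )


def load_lexicons(
    valence_path,
    emotion_path,
    synonym_path,
    antonym_path,
    stemmer: Optional[Stemmer] = None,
) -> LexiconBundle:
    """Load all four TSV resources into a bundle.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`LexiconParseError` (naming the line) for a malformed row.
    """
    stemmer = stemmer or default_stem
    return LexiconBundle(
        valence=load_valence_norms(valence_path),
        emotions=load_emotion_lexicon(emotion_path, stemmer=stemmer),
        synonyms=load_pair_lexicon(synonym_path),
        antonyms=load_pair_lexicon(antonym_path),
        stemmer=stemmer,
    )


def stem_aggregate_valence(
    norms: ValenceNorms, stemmer: Optional[Stemmer] = None
) -> StemValenceTable:
    """Average valence scores over words sharing a stemmed root."""
    if not norms.entries:
        raise ValueError("empty valence norms")
    stemmer = stemmer or default_stem
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for word, score in norms.entries.items():
        s = stemmer(word)
        sums[s] = sums.get(s, 0.0) + score
        counts[s] = counts.get(s, 0) + 1
    return StemValenceTable({s: sums[s] / counts[s] for s in sums})


def assign_valence_labels(table: StemValenceTable) -> ValenceLabelMap:
    """Quartile-split stem scores into positive / neutral / negative.

    q1 and q3 are the 25th/75th percentiles of the stem-score
    distribution under linear interpolation; labels use strict
    inequalities so quartile ties are neutral.
    """
    scores = np.asarray(list(table.entries.values()), dtype=float)
    if scores.size < 4:
        raise ValueError(
            f"need at least 4 stems for quartile labelling, got {scores.size}"
        )
    q1, q3 = np.percentile(scores, [25.0, 75.0], method="linear")
    labels = {}
    for s, v in table.entries.items():
        if v > q3:
            labels[s] = POSITIVE
        elif v < q1:
            labels[s] = NEGATIVE
        else:
            labels[s] = NEUTRAL
    return ValenceLabelMap(labels, q1=float(q1), q3=float(q3))


def emotions_of(lex: EmotionLexicon, word: str) -> FrozenSet[str]:
    """Emotions evoked by a word; tries the stemmed form on a miss."""
    return lex.emotions_of(word)
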