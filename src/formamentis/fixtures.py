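"""Offline determinism: a rule-based dependency parser, mini-lexicons and
planted-topic corpora.

Every stage of the pipeline is testable without downloads or models:

* :func:`fallback_parse` is a deterministic parser for a tiny grammar
  (optional determiners, SVO order, copulas/auxiliaries, prepositional
  phrases, "not") producing UD-style trees. It is *not* a general English
  parser — real corpora should route through a pluggable UD backend —
  but it parses the worked constructions that define the contraction
  semantics ("love is weakness", "the cat sat on the chair") correctly.
* :func:`make_mini_lexicons` builds a seeded lexicon bundle whose
  quartile valence labels hit requested class sizes exactly, with
  emotion tags at exact planted base rates and planted synonym/antonym
  pairs, all returned with ground truth for assertions.
* :func:`make_topic_corpus` plants topic structure: each topic's
  documents pair the topic word with its associates through copular
  sentences, fillers hang off the periphery, and a matching reference
  association network wires associates at distance 1 from their topic
  and fillers three steps away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .corpus import Document
from .lexicons import (
    EMOTIONS,
    EmotionLexicon,
    LexiconBundle,
    PairLexicon,
    ValenceNorms,
)
from .stemming import stem as default_stem
from .syntax import DepGraph, Token

__all__ = [
    "FixtureSpec",
    "MiniLexicons",
    "TopicCorpus",
    "fallback_parse",
    "make_mini_lexicons",
    "make_topic_corpus",
    "make_lexical_corpus",
    "write_lexicon_tsvs",
    "write_topic_corpus",
]

# ---------------------------------------------------------------------------
# Fallback parser
# ---------------------------------------------------------------------------

_DET = frozenset(
    "the a an this that these those my your our their her his its some any each every".split()
)
_ADP = frozenset(
    "on in at of with to for from by about over under into through between against during "
    "within without across behind beyond after before around near".split()
)
_AUX = frozenset(
    "is are was were be been being am do does did have has had can could will would "
    "shall should may might must".split()
)
_CCONJ = frozenset("and or but nor yet".split())
_SCONJ = frozenset("because if while although unless since whereas".split())
_NEG = frozenset(("not", "n't", "nt"))

_IRREGULAR_LEMMA = {
    "sat": "sit", "was": "be", "were": "be", "is": "be", "are": "be", "am": "be",
    "been": "be", "being": "be", "has": "have", "had": "have", "did": "do",
    "does": "do", "ran": "run", "men": "man", "women": "woman",
    "children": "child", "went": "go", "said": "say", "made": "make",
    "got": "get", "thought": "think", "took": "take", "saw": "see",
    "knew": "know", "felt": "feel", "found": "find", "gave": "give",
    "told": "tell", "became": "become", "left": "leave", "kept": "keep",
    "n't": "not", "nt": "not",
}

_PUNCT_CHARS = ".,;:!?\"'()[]{}"


def _tokenize(sentence: str) -> List[Tuple[str, str]]:
    """Split into (surface, coarse POS) pairs over the fixture grammar."""
    out: List[Tuple[str, str]] = []
    for raw in sentence.split():
        core = raw.strip(_PUNCT_CHARS)
        if not core:
            out.append((raw, "PUNCT"))
            continue
        if core.lower().endswith("n't") and len(core) > 3:
            _append_word(out, core[:-3])
            out.append(("n't", "PART"))
            continue
        _append_word(out, core)
    return out


def _append_word(out: List[Tuple[str, str]], word: str) -> None:
    w = word.lower()
    if w in _NEG:
        out.append((word, "PART"))
    elif w in _DET:
        out.append((word, "DET"))
    elif w in _ADP:
        out.append((word, "ADP"))
    elif w in _AUX:
        out.append((word, "AUX"))
    elif w in _CCONJ:
        out.append((word, "CCONJ"))
    elif w in _SCONJ:
        out.append((word, "SCONJ"))
    else:
        out.append((word, "NOUN"))  # content; verbhood is positional


def fallback_parse(sentence: str) -> DepGraph:
    """Deterministic UD-style parse of a fixture-grammar sentence.

    Rules: the first content word is the subject; a copula/auxiliary run
    before the next content word makes that word the root (``cop``/
    ``aux`` arcs); otherwise the second content word is the root verb
    with ``nsubj``/``obj`` arcs; ``ADP [DET] word`` yields ``case`` +
    ``obl``; determiners attach forward (``det``); "not" attaches to the
    next content word (``advmod``). Tokens outside the closed lists are
    tagged NOUN — the parser never fails on unknown vocabulary.
    """
    if not sentence or not sentence.strip():
        raise ValueError("cannot parse an empty sentence")
    tagged = _tokenize(sentence)
    tokens = []
    for i, (surface, pos) in enumerate(tagged):
        lemma = _IRREGULAR_LEMMA.get(surface.lower(), surface.lower())
        tokens.append(Token(index=i, surface=surface, lemma=lemma, pos=pos))

    content = [t.index for t in tokens if tokens[t.index].pos == "NOUN"]
    edges: Set[Tuple[int, int, str]] = set()
    head: Dict[int, int] = {}

    def attach(h: int, d: int, rel: str) -> None:
        if d not in head and d != h:
            head[d] = h
            edges.add((h, d, rel))

    if not content:
        root = tokens[0].index if tokens else 0
    else:
        subj = content[0]
        root = subj
        if len(content) >= 2:
            between = [t for t in tokens if subj < t.index < content[1]]
            if any(t.pos == "AUX" for t in between):
                root = content[1]
                for t in between:
                    if t.pos == "AUX":
                        attach(root, t.index, "cop")
                attach(root, subj, "nsubj")
            else:
                root = content[1]
                attach(root, subj, "nsubj")

        # verbhood is positional: a root with a subject acts as predicate
        has_obj = False
        for idx in content:
            if idx in (subj, root):
                continue
            # an ADP with no content word between it and idx marks a PP
            adp = next(
                (t for t in reversed(tokens[:idx])
                 if t.pos == "ADP" and not any(t.index < c < idx for c in content)),
                None,
            )
            if adp is not None and adp.index > root:
                attach(idx, adp.index, "case")
                attach(root, idx, "obl")
            elif not has_obj and idx > root:
                attach(root, idx, "obj")
                has_obj = True
            else:
                attach(root, idx, "dep")

    # determiners attach to the next content word
    for t in tokens:
        if t.pos == "DET":
            nxt = next((c for c in content if c > t.index), root)
            attach(nxt, t.index, "det")
    # negation attaches to the next content word (or the root)
    for t in tokens:
        if t.pos == "PART":
            nxt = next((c for c in content if c > t.index), root)
            attach(nxt, t.index, "advmod")
    # everything else hangs off the root
    for t in tokens:
        if t.index != root and t.index not in head:
            attach(root, t.index, "dep")

    return DepGraph(tokens=tuple(tokens), edges=frozenset(edges))


# ---------------------------------------------------------------------------
# Synthetic word stock
# ---------------------------------------------------------------------------

_ONSETS = "b d f g k l m n p r s t v z bl br dr fl gr kl pr st tr".split()
_VOWELS_SYL = "a e i o u".split()


def _word_stock(rng: np.random.Generator, count: int, taken: Set[str]) -> List[str]:
    """Generate pronounceable synthetic words that are stemmer fixed points
    with pairwise-distinct stems (so network nodes equal surface forms)."""
    words: List[str] = []
    stems_seen = {default_stem(w) for w in taken}
    guard = 0
    while len(words) < count:
        guard += 1
        if guard > 200000:
            raise RuntimeError("word stock generation stalled")
        n_syl = int(rng.integers(2, 4))
        w = "".join(
            _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS_SYL[rng.integers(len(_VOWELS_SYL))]
            for _ in range(n_syl)
        )
        s = default_stem(w)
        if s == w and s not in stems_seen and w not in _AUX and w not in _DET:
            stems_seen.add(s)
            words.append(w)
            taken.add(w)
    return words


# ---------------------------------------------------------------------------
# Fixture specification
# ---------------------------------------------------------------------------

_DEFAULT_EMOTION_RATES: Dict[str, float] = {
    # unequal base rates, echoing real emotion lexicons where fear/trust/joy
    # tag more words than sadness or anticipation
    "anger": 0.20,
    "disgust": 0.18,
    "fear": 0.30,
    "trust": 0.35,
    "joy": 0.30,
    "sadness": 0.16,
    "surprise": 0.18,
    "anticipation": 0.22,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    n_positive: int = 10
    n_neutral: int = 20
    n_negative: int = 10
    emotion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EMOTION_RATES)
    )
    n_synonym_pairs: int = 6
    n_antonym_pairs: int = 6
    n_topics: int = 3
    docs_per_topic: int = 5
    words_per_doc: int = 18
    n_associates: int = 8
    negation_rate: float = 0.1

    def __post_init__(self):
        if any(v < 0 for v in (self.n_positive, self.n_neutral, self.n_negative)):
            raise ValueError("class sizes must be non-negative")
        for e, r in self.emotion_rates.items():
            if e not in EMOTIONS:
                raise ValueError(f"unknown emotion {e!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"base rate for {e} outside [0,1]")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ValueError("negation rate outside [0,1]")


@dataclass(frozen=True)
class MiniLexicons:
    """A lexicon bundle plus the ground truth it was built from."""

    bundle: LexiconBundle
    true_labels: Mapping[str, str]            # word -> planted valence class
    true_emotions: Mapping[str, FrozenSet[str]]
    synonym_pairs: FrozenSet[Tuple[str, str]]
    antonym_pairs: FrozenSet[Tuple[str, str]]


def _quartile_scores(n_neg: int, n_neut: int, n_pos: int) -> np.ndarray:
    """Sorted score vector whose strict-quartile labelling yields exactly
    the requested class sizes, using plateaus at q1/q3 where needed."""
    n = n_neg + n_neut + n_pos
    if n < 4:
        raise ValueError("need at least 4 stems in total")
    q1v, q3v = 3.0, 7.0
    h1, h3 = 0.25 * (n - 1), 0.75 * (n - 1)
    fl1, fl3 = math.floor(h1), math.floor(h3)

    neg_distinct = fl1 if h1.is_integer() else fl1 + 1
    pos_distinct = (n - 1 - fl3) if h3.is_integer() else (n - 1 - fl3 - 1) + 1
    # n - 1 - fl3 when h3 is an integer counts indices > h3; otherwise
    # q1 interpolates inside (x_fl3, x_fl3+1) so indices fl3+1..n-1 lie above.
    if not h3.is_integer():
        pos_distinct = n - 1 - fl3

    if n_neg == neg_distinct:
        p1 = 0
    elif n_neg < neg_distinct:
        last = fl1 if h1.is_integer() else fl1 + 1
        p1 = last - n_neg + 1
    else:
        raise ValueError(
            f"infeasible spec: at most {neg_distinct} negative stems out of {n}"
        )
    if n_pos == pos_distinct:
        p2 = 0
    elif n_pos < pos_distinct:
        first = fl3 if not h3.is_integer() else fl3
        p2 = (n - n_pos - 1) - first + 1
    else:
        raise ValueError(
            f"infeasible spec: at most {pos_distinct} positive stems out of {n}"
        )
    mid = n - n_neg - n_pos - p1 - p2
    if mid < 0:
        raise ValueError("infeasible spec: quartile plateaus overlap")
    scores = np.concatenate(
        [
            np.linspace(1.0, 2.8, n_neg) if n_neg else np.empty(0),
            np.full(p1, q1v),
            np.linspace(3.2, 6.8, mid) if mid else np.empty(0),
            np.full(p2, q3v),
            np.linspace(7.2, 9.0, n_pos) if n_pos else np.empty(0),
        ]
    )
    assert scores.size == n
    return scores


def make_mini_lexicons(spec: FixtureSpec) -> MiniLexicons:
    """Build a seeded lexicon bundle with exact planted structure."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positive + spec.n_neutral + spec.n_negative
    taken: Set[str] = set()
    words = _word_stock(rng, n, taken)

    scores = _quartile_scores(spec.n_negative, spec.n_neutral, spec.n_positive)
    order = rng.permutation(n)
    shuffled = [words[i] for i in order]
    valence_entries = {w: float(scores[k]) for k, w in enumerate(shuffled)}
    true_labels = {}
    for k, w in enumerate(shuffled):
        if k < spec.n_negative:
            true_labels[w] = "negative"
        elif k >= n - spec.n_positive:
            true_labels[w] = "positive"
        else:
            true_labels[w] = "neutral"

    emo_entries: Dict[str, Set[str]] = {w: set() for w in words}
    for emotion in EMOTIONS:
        rate = spec.emotion_rates.get(emotion, 0.0)
        k = int(round(rate * n))
        for w in rng.choice(words, size=k, replace=False):
            emo_entries[str(w)].add(emotion)
    true_emotions = {w: frozenset(e) for w, e in emo_entries.items()}

    shuffled2 = [words[i] for i in rng.permutation(n)]
    syn_pairs = set()
    i = 0
    while len(syn_pairs) < spec.n_synonym_pairs and i + 1 < n:
        a, b = shuffled2[i], shuffled2[i + 1]
        syn_pairs.add((min(a, b), max(a, b)))
        i += 2
    pos_words = [w for w in words if true_labels[w] == "positive"]
    neg_words = [w for w in words if true_labels[w] == "negative"]
    ant_pairs = set()
    for j in range(min(spec.n_antonym_pairs, len(pos_words), len(neg_words))):
        a, b = pos_words[j], neg_words[j]
        ant_pairs.add((min(a, b), max(a, b)))

    bundle = LexiconBundle(
        valence=ValenceNorms(valence_entries),
        emotions=EmotionLexicon({w: set(e) for w, e in emo_entries.items() if e}),
        synonyms=PairLexicon(frozenset(syn_pairs)),
        antonyms=PairLexicon(frozenset(ant_pairs)),
    )
    return MiniLexicons(
        bundle=bundle,
        true_labels=true_labels,
        true_emotions=true_emotions,
        synonym_pairs=frozenset(syn_pairs),
        antonym_pairs=frozenset(ant_pairs),
    )


# ---------------------------------------------------------------------------
# Planted-topic corpus
# ---------------------------------------------------------------------------

_REFERENCE_HUB = "science"
_REFERENCE_MISC = "misc"


@dataclass(frozen=True)
class TopicCorpus:
    """Documents grouped by topic plus the matching reference network."""

    documents_by_topic: Mapping[str, Tuple[Document, ...]]
    reference_edges: FrozenSet[Tuple[str, str]]
    topics: Tuple[str, ...]
    associates: Mapping[str, Tuple[str, ...]]
    fillers: Mapping[str, Tuple[str, ...]]


def make_topic_corpus(spec: FixtureSpec) -> TopicCorpus:
    """Generate a corpus with planted topic structure.

    Each topic word appears in copular sentences with its associates
    ("<topic> is <associate>"), so after contraction the topic sits at
    the centre of its network. Filler words hang off associates in
    chains ("<associate> is <filler>", "<filler> is <filler2>"), giving
    them the degree profile of associates but a peripheral position.
    The emitted reference network places associates at distance 1 from
    their own topic and fillers at distance 3, so closeness rankings on
    the real networks land near the topic while rankings on rewired
    networks drift towards fillers.
    """
    rng = np.random.default_rng(spec.seed + 1)
    taken: Set[str] = {_REFERENCE_HUB, _REFERENCE_MISC}
    topics = tuple(_word_stock(rng, spec.n_topics, taken))
    associates: Dict[str, Tuple[str, ...]] = {}
    fillers: Dict[str, Tuple[str, ...]] = {}
    docs: Dict[str, Tuple[Document, ...]] = {}
    ref_edges: Set[Tuple[str, str]] = set()

    for t in topics:
        ref_edges.add((min(t, _REFERENCE_HUB), max(t, _REFERENCE_HUB)))
    ref_edges.add((min(_REFERENCE_HUB, _REFERENCE_MISC), max(_REFERENCE_HUB, _REFERENCE_MISC)))

    for t in topics:
        assoc = tuple(_word_stock(rng, spec.n_associates, taken))
        f1 = tuple(_word_stock(rng, spec.n_associates, taken))
        f2 = tuple(_word_stock(rng, spec.n_associates, taken))
        f3 = tuple(_word_stock(rng, max(spec.n_associates // 2, 1), taken))
        all_fillers = f1 + f2 + f3
        associates[t] = assoc
        fillers[t] = all_fillers

        for a in assoc:
            ref_edges.add((min(t, a), max(t, a)))
        for f in all_fillers:
            ref_edges.add((min(f, _REFERENCE_MISC), max(f, _REFERENCE_MISC)))

        sentences: List[str] = []
        for i, a in enumerate(assoc):
            if rng.random() < spec.negation_rate:
                sentences.append(f"{t} is not {a}")
            else:
                sentences.append(f"{t} is {a}")
            sentences.append(f"{a} is {f1[i]}")
            sentences.append(f"{f1[i]} is {f2[i]}")
        for j, f in enumerate(f3):
            sentences.append(f"{f2[j]} is {f}")

        doc_sents: List[List[str]] = [[] for _ in range(spec.docs_per_topic)]
        for i, s in enumerate(sentences):
            doc_sents[i % spec.docs_per_topic].append(s)
        for d in doc_sents:
            while sum(len(s.split()) for s in d) < spec.words_per_doc:
                a = assoc[int(rng.integers(len(assoc)))]
                d.append(f"{t} is {a}")
        docs[t] = tuple(
            Document.from_raw(f"{t}-{k}", ". ".join(d) + ".")
            for k, d in enumerate(doc_sents)
        )

    return TopicCorpus(
        documents_by_topic=docs,
        reference_edges=frozenset(ref_edges),
        topics=topics,
        associates=associates,
        fillers=fillers,
    )


def make_lexical_corpus(
    mini: MiniLexicons, seed: int = 0, n_extra: int = 20
) -> Tuple[Document, ...]:
    """Documents drawn from the lexicon's own vocabulary.

    Every planted synonym and antonym pair appears together in a copular
    sentence, so a network built from this corpus carries valence labels
    on all nodes and realises the full planted synonym layer. ``n_extra``
    additional random word pairings thicken the syntactic layer.
    """
    rng = np.random.default_rng(seed)
    words = sorted(mini.bundle.valence.entries)
    sentences: List[str] = []
    for a, b in sorted(mini.synonym_pairs | mini.antonym_pairs):
        sentences.append(f"{a} is {b}")
    for _ in range(n_extra):
        a, b = rng.choice(words, size=2, replace=False)
        if a != b:
            sentences.append(f"{a} is {b}")
    docs = []
    for k in range(0, len(sentences), 2):
        chunk = sentences[k:k + 2]
        docs.append(Document.from_raw(f"lex-{k // 2}", ". ".join(chunk) + "."))
    return tuple(docs)


# ---------------------------------------------------------------------------
# Writers (generators emit the same formats the loaders read)
# ---------------------------------------------------------------------------

def write_lexicon_tsvs(mini: MiniLexicons, out_dir) -> Dict[str, Path]:
    """Dump the bundle as the four loader-compatible TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out_dir / "valence.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for w in sorted(mini.bundle.valence.entries):
            fh.write(f"{w}\t{mini.bundle.valence.entries[w]:.6f}\n")
    paths["valence"] = p

    p = out_dir / "emotions.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for w in sorted(mini.bundle.emotions.entries):
            for e in sorted(mini.bundle.emotions.entries[w]):
                fh.write(f"{w}\t{e}\n")
    paths["emotions"] = p

    for name, lex in (("synonyms", mini.bundle.synonyms), ("antonyms", mini.bundle.antonyms)):
        p = out_dir / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            for a, b in sorted(lex.pairs):
                fh.write(f"{a}\t{b}\n")
        paths[name] = p
    return paths


def write_topic_corpus(corpus: TopicCorpus, out_dir) -> Dict[str, Path]:
    """Dump per-topic text files and the reference edge list (TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for t, documents in corpus.documents_by_topic.items():
        p = out_dir / f"{t}.txt"
        with open(p, "w", encoding="utf-8") as fh:
            for d in documents:
                fh.write(d.raw + "\n")
        paths[t] = p
    p = out_dir / "reference_edges.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        for a, b in sorted(corpus.reference_edges):
            fh.write(f"{a}\t{b}\n")
    paths["reference"] = p
    return paths
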