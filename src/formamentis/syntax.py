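"""From dependency parses to content-word edges.

A sentence is parsed into a Universal-Dependencies-style tree; function
words (determiners, adpositions, auxiliaries, conjunctions, punctuation)
carry no standalone meaning and are removed as nodes, each one replaced
by links bridging its dependency neighbours. In "love is weakness" the
copula drops out and "love" links directly to "weakness"; in "the cat
sat on the chair", "cat" and "chair" stay connected through the content
verb "sit". The negation particle "not" is deliberately kept as a node:
it modifies meaning and feeds the antonym expansion of emotional
profiling downstream.

Parser backends are pluggable: anything mapping a sentence to tokens
``(index, surface, lemma, coarse POS)`` plus head→dependent arcs
satisfies the contract. The offline rule-based backend lives in
:mod:`formamentis.fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, FrozenSet, List, Optional, Set, Tuple

from .stemming import Stemmer, stem as default_stem

__all__ = [
    "Token",
    "DepGraph",
    "ParserBackend",
    "REMOVED_POS",
    "NEGATION_WORDS",
    "parse_dependencies",
    "contract_function_words",
    "stem_edges",
]

#: UD coarse POS tags removed as nodes during contraction. PART is in
#: the set but negation particles are exempted (see NEGATION_WORDS).
REMOVED_POS: FrozenSet[str] = frozenset(
    {"ADP", "AUX", "DET", "PART", "PUNCT", "CCONJ", "SCONJ", "SYM", "X"}
)

#: Surface forms of the negation particle, always kept as nodes.
NEGATION_WORDS: FrozenSet[str] = frozenset({"not", "n't", "nt"})


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    pos: str  # UD coarse tag


@dataclass(frozen=True)
class DepGraph:
    """Tokens plus directed head→dependent arcs (a tree or forest)."""

    tokens: Tuple[Token, ...]
    edges: FrozenSet[Tuple[int, int, str]]  # (head index, dependent index, relation)

    def __post_init__(self):
        n = len(self.tokens)
        for h, d, _ in self.edges:
            if not (0 <= h < n and 0 <= d < n):
                raise ValueError(f"arc ({h},{d}) references a missing token")


ParserBackend = Callable[[str], DepGraph]


def parse_dependencies(sentence: str, parser_backend: ParserBackend) -> DepGraph:
    """Parse one sentence with the given backend."""
    if not sentence or not sentence.strip():
        raise ValueError("cannot parse an empty sentence")
    if parser_backend is None:
        raise ValueError(
            "no parser backend available; use formamentis.fixtures.fallback_parse "
            "or plug in any UD-style parser"
        )
    return parser_backend(sentence)


def _is_removed(tok: Token) -> bool:
    if tok.surface.lower() in NEGATION_WORDS or tok.lemma.lower() in NEGATION_WORDS:
        return False
    return tok.pos in REMOVED_POS


def contract_function_words(dep: DepGraph) -> Set[Tuple[str, str]]:
    """Delete function-word nodes, bridging their neighbours transitively.

    Chains of deleted nodes collapse: any two content words connected
    through function words end up directly linked. Returns unordered
    lemma pairs (lowercase), self-pairs dropped.
    """
    adj: dict = {t.index: set() for t in dep.tokens}
    for h, d, _ in dep.edges:
        adj[h].add(d)
        adj[d].add(h)

    for tok in dep.tokens:
        if _is_removed(tok):
            i = tok.index
            nbrs = adj.pop(i)
            for n in nbrs:
                adj[n].discard(i)
            for a in nbrs:
                if a in adj:
                    for b in nbrs:
                        if b in adj and a != b:
                            adj[a].add(b)
                            adj[b].add(a)

    lemma = {t.index: (t.lemma or t.surface).lower() for t in dep.tokens}
    out: Set[Tuple[str, str]] = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            if lemma[i] != lemma[j]:
                out.add((min(lemma[i], lemma[j]), max(lemma[i], lemma[j])))
    return out


def stem_edges(
    edges: Set[Tuple[str, str]], stemmer: Optional[Stemmer] = None
) -> Set[Tuple[str, str]]:
    """Map edge endpoints to stems; drop collapsed self-loops, merge duplicates."""
    stemmer = stemmer or default_stem
    out: Set[Tuple[str, str]] = set()
    for a, b in edges:
        sa, sb = stemmer(a), stemmer(b)
        if sa != sb:
            out.add((min(sa, sb), max(sa, sb)))
    return out
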