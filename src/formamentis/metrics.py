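"""Graph measures for forma mentis analysis.

Closeness here follows the component-relative form

    c(i) = N / sum_j d_ij

where N is the size of i's connected component and d_ij the
shortest-path (link-count) distance within it. This differs from the
conventional (N-1)/sum(d) by a constant factor inside a component; the
conventional variant is available behind a flag. Because the formula is
only comparable within one component, rankings are restricted to the
largest connected component of the aggregate graph.

Structural nulls are configuration models: seeded degree-preserving
double-edge-swap randomisations with 10|E| attempted swaps. Graphs
whose degree sequence admits a unique simple realisation (stars,
triangles) come back unchanged.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np
from scipy import stats

from .lexicons import NEGATIVE, NEUTRAL, POSITIVE, UNKNOWN, ValenceLabelMap
from .network import TFMN, aggregate_graph
from .stemming import Stemmer, stem as default_stem
from .syntax import contract_function_words
from .corpus import Document

__all__ = [
    "ClosenessScore",
    "ValenceAura",
    "ValenceFrequencySummary",
    "ValenceClassComparison",
    "shortest_path_distance",
    "closeness",
    "closeness_ranking",
    "valence_aura",
    "mean_clustering",
    "rewire_configuration",
    "null_clustering",
    "detect_communities",
    "valence_class_comparison",
    "valence_frequency_summary",
]


# ---------------------------------------------------------------------------
# Distance and closeness
# ---------------------------------------------------------------------------

def shortest_path_distance(graph: nx.Graph, i, j) -> Optional[int]:
    """BFS link-count distance; ``None`` when j is unreachable from i."""
    if i not in graph or j not in graph:
        raise KeyError(f"node missing from graph: {i if i not in graph else j!r}")
    try:
        return nx.shortest_path_length(graph, i, j)
    except nx.NetworkXNoPath:
        return None


@dataclass(frozen=True)
class ClosenessScore:
    """Component-relative closeness of one node.

    ``value = component_size / sum_distance`` held exactly as the two
    integers; ``defined`` is False for singleton components (zero
    distance sum).
    """

    node: str
    component_size: int
    sum_distance: int
    conventional: bool = False

    @property
    def defined(self) -> bool:
        return self.sum_distance > 0

    @property
    def value(self) -> float:
        if not self.defined:
            return float("nan")
        num = self.component_size - 1 if self.conventional else self.component_size
        return num / self.sum_distance

    @property
    def exact(self) -> Fraction:
        if not self.defined:
            raise ZeroDivisionError("closeness undefined for a singleton component")
        num = self.component_size - 1 if self.conventional else self.component_size
        return Fraction(num, self.sum_distance)


def closeness(graph: nx.Graph, i, conventional: bool = False) -> ClosenessScore:
    """Closeness of node ``i`` within its own connected component."""
    if i not in graph:
        raise KeyError(f"node {i!r} not in graph")
    lengths = nx.single_source_shortest_path_length(graph, i)
    return ClosenessScore(
        node=i,
        component_size=len(lengths),
        sum_distance=sum(lengths.values()),
        conventional=conventional,
    )


def closeness_ranking(
    network: Union[TFMN, nx.Graph], k: Optional[int] = None, conventional: bool = False
) -> List[Tuple[str, float]]:
    """Top-``k`` concepts by closeness on the largest connected component.

    Cross-component closeness values are not comparable (the component
    size enters the formula), so the ranking is computed on the largest
    component only. Ties break lexicographically; ``k`` beyond the
    component size returns the full ranking.
    """
    g = aggregate_graph(network) if isinstance(network, TFMN) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    giant = max(nx.connected_components(g), key=len)
    sub = g.subgraph(giant)
    scores = []
    for n in sub.nodes:
        s = closeness(sub, n, conventional=conventional)
        scores.append((n, s.value if s.defined else 0.0, s))
    scores.sort(key=lambda t: (-t[1], t[0]))
    ranked = [(n, v) for n, v, _ in scores]
    return ranked if k is None else ranked[:k]


# ---------------------------------------------------------------------------
# Valence auras
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValenceAura:
    """Modal valence among a concept's neighbours.

    ``fractions`` sum to 1 over {positive, neutral, negative} (unknown
    neighbours count as neutral); ``aura`` is the arg-max label, or
    ``"mixed"`` when the maximum is tied.
    """

    focus: str
    fractions: Mapping[str, float]
    aura: str


def valence_aura(tfmn: TFMN, focus: str) -> ValenceAura:
    if focus not in tfmn.nodes:
        raise KeyError(f"focus {focus!r} not in network")
    g = aggregate_graph(tfmn)
    nbrs = list(g.neighbors(focus))
    if not nbrs:
        raise ValueError(f"focus {focus!r} is isolated; aura undefined")
    counts = {POSITIVE: 0, NEUTRAL: 0, NEGATIVE: 0}
    for n in nbrs:
        label = tfmn.valence.get(n, UNKNOWN)
        counts[NEUTRAL if label == UNKNOWN else label] += 1
    total = len(nbrs)
    fractions = {lab: c / total for lab, c in counts.items()}
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return ValenceAura(
        focus=focus,
        fractions=fractions,
        aura=winners[0] if len(winners) == 1 else "mixed",
    )


# ---------------------------------------------------------------------------
# Clustering and configuration-model nulls
# ---------------------------------------------------------------------------

def mean_clustering(graph: nx.Graph) -> float:
    """Mean local clustering coefficient (degree <2 nodes contribute 0)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    coeffs = nx.clustering(graph)
    # summation in sorted node order keeps the float result independent
    # of graph insertion order
    return sum(coeffs[n] for n in sorted(graph.nodes, key=str)) / graph.number_of_nodes()


def rewire_configuration(graph: nx.Graph, seed: int) -> nx.Graph:
    """Degree-preserving randomisation by double edge swaps.

    Attempts ``10 |E|`` swaps; a swap is skipped whenever it would
    create a self-loop or a multi-edge, so degree sequences with a
    unique simple realisation return the input graph unchanged.
    """
    if graph.number_of_edges() < 2:
        return graph.copy()
    rng = random.Random(seed)
    g = graph.copy()
    # canonical edge list: endpoint-sorted tuples in sorted order, so the
    # swap sequence is independent of graph insertion order
    edges = sorted(tuple(sorted(e, key=str)) for e in g.edges())
    n_attempts = 10 * len(edges)
    for _ in range(n_attempts):
        (a, b), (c, d) = rng.sample(edges, 2)
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-c, b-d replacing a-b, c-d
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, c) or g.has_edge(b, d):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, c)
        g.add_edge(b, d)
        edges.remove((a, b) if (a, b) in edges else (b, a))
        edges.remove((c, d) if (c, d) in edges else (d, c))
        edges.append(tuple(sorted((a, c), key=str)))
        edges.append(tuple(sorted((b, d), key=str)))
    return g


def null_clustering(
    graph: nx.Graph, realizations: int, seed: int
) -> Tuple[float, float]:
    """Mean and sd of mean clustering over configuration-model rewirings."""
    if realizations < 2:
        raise ValueError("need at least 2 realizations")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(realizations):
        sub_seed = int(rng.integers(2**31 - 1))
        values.append(mean_clustering(rewire_configuration(graph, sub_seed)))
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1))


def detect_communities(graph: nx.Graph, seed: int = 0) -> Dict[str, int]:
    """Louvain modularity partition, seeded for reproducibility."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.algorithms.community.louvain_communities(graph, seed=seed)
    # deterministic community ids: order by smallest member
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {n: cid for cid, members in enumerate(comms) for n in members}


# ---------------------------------------------------------------------------
# Valence-class comparisons and frequency summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValenceClassComparison:
    """Positive vs negative nodes: degree and closeness location tests."""

    n_positive: int
    n_negative: int
    median_degree: Mapping[str, float]
    median_closeness: Mapping[str, float]
    degree_u: float
    degree_p: float
    closeness_u: float
    closeness_p: float


def valence_class_comparison(tfmn: TFMN) -> ValenceClassComparison:
    """Compare degree and closeness distributions of positive vs negative
    concepts (two-sided Mann–Whitney; closeness on the largest component).

    Unknown-valence nodes are excluded throughout.
    """
    g = aggregate_graph(tfmn)
    pos = [n for n in tfmn.nodes if tfmn.valence[n] == POSITIVE]
    neg = [n for n in tfmn.nodes if tfmn.valence[n] == NEGATIVE]
    if not pos or not neg:
        raise ValueError("need at least one node in each valence class")
    deg_pos = [g.degree(n) for n in pos]
    deg_neg = [g.degree(n) for n in neg]
    from .benchmark import mann_whitney_u

    du, dp = mann_whitney_u(deg_pos, deg_neg)

    giant = max(nx.connected_components(g), key=len)
    sub = g.subgraph(giant)
    clo = {n: closeness(sub, n).value for n in sub.nodes if sub.degree(n) > 0}
    clo_pos = [clo[n] for n in pos if n in clo]
    clo_neg = [clo[n] for n in neg if n in clo]
    if clo_pos and clo_neg:
        cu, cp = mann_whitney_u(clo_pos, clo_neg)
    else:
        cu, cp = float("nan"), float("nan")
    return ValenceClassComparison(
        n_positive=len(pos),
        n_negative=len(neg),
        median_degree={
            POSITIVE: float(np.median(deg_pos)),
            NEGATIVE: float(np.median(deg_neg)),
        },
        median_closeness={
            POSITIVE: float(np.median(clo_pos)) if clo_pos else float("nan"),
            NEGATIVE: float(np.median(clo_neg)) if clo_neg else float("nan"),
        },
        degree_u=du,
        degree_p=dp,
        closeness_u=cu,
        closeness_p=cp,
    )


@dataclass(frozen=True)
class ValenceFrequencySummary:
    """Type and token counts of stems by valence class."""

    type_counts: Mapping[str, int]
    token_counts: Mapping[str, int]


def valence_frequency_summary(
    documents: Sequence[Document],
    labelmap: ValenceLabelMap,
    stemmer: Optional[Stemmer] = None,
    parser_backend=None,
) -> ValenceFrequencySummary:
    """Count stem occurrences across documents, split by valence class.

    Token counts run over all stemmed content tokens (function words are
    dropped via the parser backend when given, else by a whitespace
    tokenisation); type counts are distinct stems per class. Stems
    absent from the norms are tallied under ``"unknown"``.
    """
    stemmer = stemmer or default_stem
    tokens: List[str] = []
    for doc in documents:
        for sentence in doc.sentences:
            if parser_backend is not None:
                dep = parser_backend(sentence)
                kept = [
                    t.lemma for t in dep.tokens
                    if not _function_token(t)
                ]
            else:
                kept = sentence.split()
            tokens.extend(stemmer(w.lower()) for w in kept)
    type_counts = {POSITIVE: 0, NEGATIVE: 0, NEUTRAL: 0, UNKNOWN: 0}
    token_counts = {POSITIVE: 0, NEGATIVE: 0, NEUTRAL: 0, UNKNOWN: 0}
    seen: Set[str] = set()
    for s in tokens:
        lab = labelmap.label(s)
        token_counts[lab] += 1
        if s not in seen:
            seen.add(s)
            type_counts[lab] += 1
    return ValenceFrequencySummary(type_counts=type_counts, token_counts=token_counts)


def _function_token(tok) -> bool:
    from .syntax import NEGATION_WORDS, REMOVED_POS

    if tok.surface.lower() in NEGATION_WORDS or tok.lemma.lower() in NEGATION_WORDS:
        return False
    return tok.pos in REMOVED_POS
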