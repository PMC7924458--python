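"""Topic-relevance benchmark against a reference association network.

The validation logic: build one forma mentis network per topic text,
take its top-k concepts by closeness, and measure how far each ranked
concept sits from the topic word on an independent reference network of
free associations (network distance there proxies semantic
relatedness). If closeness on forma mentis networks picks out
topic-relevant words, the empirical distances should be smaller than
those obtained after degree-preserving rewiring of each network
(configuration models, re-ranking from scratch on every randomised
copy). A two-sided Mann–Whitney location test compares the pooled
empirical and null distance samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .corpus import Document
from .lexicons import LexiconBundle
from .metrics import closeness_ranking, rewire_configuration
from .network import TFMN, aggregate_graph, assemble_tfmn
from .stemming import Stemmer, stem as default_stem
from .syntax import ParserBackend

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceNetwork",
    "BenchmarkResult",
    "load_reference_network",
    "topic_distances",
    "null_topic_distances",
    "mann_whitney_u",
    "run_benchmark",
]


class ReferenceNetwork:
    """Undirected word network (e.g. free associations) with stem lookup."""

    def __init__(self, edges: Sequence[Tuple[str, str]], stemmer: Optional[Stemmer] = None):
        self._stemmer = stemmer or default_stem
        g = nx.Graph()
        for a, b in edges:
            a, b = a.lower(), b.lower()
            if a != b:
                g.add_edge(a, b)
        self.graph = g
        self._by_stem: Dict[str, str] = {}
        for w in sorted(g.nodes):
            self._by_stem.setdefault(self._stemmer(w), w)

    def resolve(self, word: str) -> Optional[str]:
        """Map a surface form or stem to a network node, None on a miss."""
        w = word.lower()
        if w in self.graph:
            return w
        return self._by_stem.get(self._stemmer(w))

    def distance(self, a: str, b: str) -> Optional[int]:
        ra, rb = self.resolve(a), self.resolve(b)
        if ra is None or rb is None:
            return None
        try:
            return nx.shortest_path_length(self.graph, ra, rb)
        except nx.NetworkXNoPath:
            return None


def load_reference_network(path, stemmer: Optional[Stemmer] = None) -> ReferenceNetwork:
    """Read a TSV edge list (two columns, '#' comments allowed)."""
    edges = []
    with open(Path(path), encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}: expected 2 columns, got {len(cols)}")
            edges.append((cols[0].strip(), cols[1].strip()))
    return ReferenceNetwork(edges, stemmer=stemmer)


def topic_distances(
    ranked_words: Sequence[str],
    reference: ReferenceNetwork,
    topic: str,
) -> List[int]:
    """Reference-network distance from each ranked word to its topic.

    The topic itself is excluded; words unresolvable on the reference
    (or disconnected from the topic) are skipped with a logged count.
    """
    rt = reference.resolve(topic)
    if rt is None:
        raise KeyError(f"topic {topic!r} not in reference network")
    out: List[int] = []
    missed = 0
    for w in ranked_words:
        rw = reference.resolve(w)
        if rw == rt:
            continue
        d = reference.distance(w, topic) if rw is not None else None
        if d is None:
            missed += 1
        else:
            out.append(d)
    if missed:
        logger.info("topic %r: %d ranked words not mapped to the reference", topic, missed)
    return out


def null_topic_distances(
    tfmns: Mapping[str, TFMN],
    reference: ReferenceNetwork,
    k: int = 10,
    realizations: int = 50,
    seed: int = 0,
) -> List[int]:
    """Pooled distances from configuration-model re-rankings.

    For every realization, each topic's aggregate network is rewired
    degree-preservingly, the top-k closeness ranking is recomputed from
    scratch on the rewired graph, and the ranked words are mapped to
    reference distances. Link reshuffling severs the tie between
    structure and meaning, so these distances are the structural null.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    rng = np.random.default_rng(seed)
    pooled: List[int] = []
    for _ in range(realizations):
        for topic in sorted(tfmns):
            sub_seed = int(rng.integers(2**31 - 1))
            g = aggregate_graph(tfmns[topic])
            rewired = rewire_configuration(g, seed=sub_seed)
            ranked = [w for w, _ in closeness_ranking(rewired, k=k)]
            pooled.extend(topic_distances(ranked, reference, topic))
    return pooled


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------

def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Mann–Whitney U of x vs y with a two-sided p-value.

    Small samples (m + n <= 10) use exact enumeration of all
    C(m+n, m) group assignments of the pooled values (ties handled by
    midranks, i.e. 1/2 contributions to U); larger samples use the
    normal approximation with tie correction. ``U + U_swapped = m*n``.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if m + n <= 10:
        pooled = x + y
        total = 0
        le = ge = 0
        for comb in itertools.combinations(range(m + n), m):
            mask = set(comb)
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in range(m + n) if i not in mask]
            u = _u_statistic(xs, ys)
            total += 1
            if u <= u_obs + 1e-12:
                le += 1
            if u >= u_obs - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le / total, ge / total))
        return u_obs, p
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Full benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkResult:
    empirical_distances: Tuple[int, ...]
    null_distances: Tuple[int, ...]
    U: float
    p: float
    median_empirical: float
    median_null: float
    realizations: int
    k: int
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def run_benchmark(
    documents_by_topic: Mapping[str, Sequence[Document]],
    reference: ReferenceNetwork,
    lexicons: LexiconBundle,
    parser_backend: ParserBackend,
    k: int = 10,
    realizations: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> BenchmarkResult:
    """Run the full topic-relevance benchmark.

    One forma mentis network is built per topic from that topic's
    documents; rankings, reference distances, configuration-model nulls
    and the location test follow.
    """
    if realizations < 1:
        raise ValueError("realizations must be >= 1")
    if not documents_by_topic:
        raise ValueError("no topics given")
    for topic in documents_by_topic:
        if reference.resolve(topic) is None:
            raise KeyError(f"topic {topic!r} not resolvable in the reference network")
        if not documents_by_topic[topic]:
            raise ValueError(f"topic {topic!r} has no documents")

    tfmns: Dict[str, TFMN] = {
        topic: assemble_tfmn(list(docs), lexicons, parser_backend)
        for topic, docs in documents_by_topic.items()
    }
    empirical: List[int] = []
    for topic in sorted(tfmns):
        ranked = [w for w, _ in closeness_ranking(tfmns[topic], k=k)]
        empirical.extend(topic_distances(ranked, reference, topic))
    null = null_topic_distances(
        tfmns, reference, k=k, realizations=realizations, seed=seed
    )
    if not empirical or not null:
        raise ValueError("no reference-mappable distances; check the reference network")
    u, p = mann_whitney_u(empirical, null)
    return BenchmarkResult(
        empirical_distances=tuple(empirical),
        null_distances=tuple(null),
        U=u,
        p=p,
        median_empirical=float(np.median(empirical)),
        median_null=float(np.median(null)),
        realizations=realizations,
        k=k,
        alpha=alpha,
    )
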