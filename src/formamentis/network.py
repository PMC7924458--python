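"""Assembly of the multiplex forma mentis network.

A TFMN has one node set (stemmed concepts) and two unweighted edge
layers: *syntactic* edges pooled from the dependency contraction of
every sentence of every document, and *synonym* edges added between any
two corpus stems listed as synonyms in the lexicon. Each node carries a
valence label (positive / neutral / negative by quartile position, or
"unknown" when the stem is missing from the norms). The two layers
share no weights or inter-layer links, so multiplex path metrics reduce
to the aggregate graph obtained by treating all edge types as
equivalent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .corpus import Document
from .lexicons import (
    UNKNOWN,
    LexiconBundle,
    PairLexicon,
    ValenceLabelMap,
    assign_valence_labels,
    stem_aggregate_valence,
)
from .stemming import Stemmer, stem as default_stem
from .syntax import ParserBackend, contract_function_words, parse_dependencies, stem_edges

logger = logging.getLogger(__name__)

__all__ = [
    "SYNTACTIC",
    "SYNONYM",
    "TFMN",
    "Frame",
    "assemble_tfmn",
    "synonym_layer",
    "aggregate_graph",
    "frame",
    "export_network",
    "import_network",
]

SYNTACTIC = "syntactic"
SYNONYM = "synonym"
_LAYERS = (SYNTACTIC, SYNONYM)


@dataclass
class TFMN:
    """Multiplex lexical network over stemmed concepts."""

    nodes: Set[str]
    valence: Dict[str, str]                      # stem -> label (incl. "unknown")
    edges: Set[Tuple[str, str, str]]             # (stem, stem, layer), pair sorted

    def __post_init__(self):
        for a, b, layer in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if layer not in _LAYERS:
                raise ValueError(f"unknown layer {layer!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a},{b}) references a missing node")

    def layer_edges(self, layer: str) -> Set[Tuple[str, str]]:
        return {(a, b) for a, b, l in self.edges if l == layer}

    @property
    def n_syntactic(self) -> int:
        return sum(1 for *_, l in self.edges if l == SYNTACTIC)

    @property
    def n_synonym(self) -> int:
        return sum(1 for *_, l in self.edges if l == SYNONYM)


@dataclass(frozen=True)
class Frame:
    """A focal concept plus its semantic frame (network neighbourhood
    or Louvain community)."""

    focus: str
    members: FrozenSet[str]
    mode: str  # "neighborhood" | "community"

    def __post_init__(self):
        if self.focus in self.members:
            raise ValueError("focus must not be one of its own frame members")


def _sorted_pair(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def synonym_layer(
    nodes: Set[str], syn: PairLexicon, stemmer: Optional[Stemmer] = None
) -> Set[Tuple[str, str, str]]:
    """Synonym edges between stems both present in ``nodes``.

    Pairs come from a surface-form synonym lexicon; both members are
    stemmed before the membership check, and no new nodes are created.
    """
    stemmer = stemmer or default_stem
    out: Set[Tuple[str, str, str]] = set()
    for a, b in syn.pairs:
        sa, sb = stemmer(a), stemmer(b)
        if sa != sb and sa in nodes and sb in nodes:
            out.add((*_sorted_pair(sa, sb), SYNONYM))
    return out


def assemble_tfmn(
    documents: Sequence[Document],
    lexicons: LexiconBundle,
    parser_backend: ParserBackend,
    label_map: Optional[ValenceLabelMap] = None,
) -> TFMN:
    """Build the full multiplex network from admitted documents.

    The syntactic layer is the union of stemmed content edges over all
    sentences of all documents, so repeated stems bridge sentences and
    documents together. The synonym layer and quartile valence labels
    are then added. A precomputed ``label_map`` may be passed; otherwise
    it is derived from the bundle's valence norms.
    """
    if not documents:
        raise ValueError("empty corpus")
    stemmer = lexicons.stemmer
    syn_edges: Set[Tuple[str, str]] = set()
    for doc in documents:
        for sentence in doc.sentences:
            dep = parse_dependencies(sentence, parser_backend)
            syn_edges |= stem_edges(contract_function_words(dep), stemmer)
    if not syn_edges:
        logger.warning("no parseable content pairs; network is empty")
    nodes = {s for pair in syn_edges for s in pair}
    edges: Set[Tuple[str, str, str]] = {
        (*_sorted_pair(a, b), SYNTACTIC) for a, b in syn_edges
    }
    edges |= synonym_layer(nodes, lexicons.synonyms, stemmer)

    if label_map is None:
        label_map = assign_valence_labels(stem_aggregate_valence(lexicons.valence, stemmer))
    valence = {s: label_map.label(s) for s in nodes}
    n_unknown = sum(1 for v in valence.values() if v == UNKNOWN)
    if n_unknown:
        logger.info("%d of %d nodes missing from the valence norms", n_unknown, len(nodes))
    return TFMN(nodes=nodes, valence=valence, edges=edges)


def aggregate_graph(tfmn: TFMN) -> nx.Graph:
    """Single-layer graph with all edge types treated as equivalent."""
    g = nx.Graph()
    # sorted insertion keeps downstream seeded algorithms (Louvain,
    # rewiring) reproducible across processes
    g.add_nodes_from(sorted(tfmn.nodes))
    for a, b in sorted({(a, b) for a, b, _ in tfmn.edges}):
        g.add_edge(a, b)
    return g


def frame(tfmn: TFMN, focus: str, mode: str = "neighborhood", seed: int = 0) -> Frame:
    """Semantic frame of ``focus``: its aggregate-graph neighbourhood, or
    its Louvain community (minus the focus itself)."""
    if focus not in tfmn.nodes:
        raise KeyError(f"focus {focus!r} not in network")
    g = aggregate_graph(tfmn)
    if mode == "neighborhood":
        members = frozenset(g.neighbors(focus))
    elif mode == "community":
        from .metrics import detect_communities

        partition = detect_communities(g, seed=seed)
        cid = partition[focus]
        members = frozenset(n for n, c in partition.items() if c == cid and n != focus)
    else:
        raise ValueError(f"unknown frame mode {mode!r}")
    return Frame(focus=focus, members=members, mode=mode)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(tfmn: TFMN, format: str, path) -> Path:
    """Write the network as GraphML, TSV edge list, or a JSON report.

    GraphML carries the node attribute ``valence`` and edge attribute
    ``layer``; the edge list is ``source<TAB>target<TAB>layer`` with a
    header; the JSON report follows the schema shipped in
    ``formamentis/data/network_schema.json``. All three round-trip
    through :func:`import_network`.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for n in sorted(tfmn.nodes):
            g.add_node(n, valence=tfmn.valence[n])
        multi = {}
        for a, b, layer in tfmn.edges:
            multi.setdefault((a, b), []).append(layer)
        for (a, b), layers in sorted(multi.items()):
            g.add_edge(a, b, layer="+".join(sorted(layers)))
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tlayer\n")
            for a, b, layer in sorted(tfmn.edges):
                fh.write(f"{a}\t{b}\t{layer}\n")
    elif format == "json":
        report = {
            "nodes": [
                {"id": n, "valence": tfmn.valence[n]} for n in sorted(tfmn.nodes)
            ],
            "edges": [
                {"source": a, "target": b, "layer": layer}
                for a, b, layer in sorted(tfmn.edges)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_network(format: str, path) -> TFMN:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = set(g.nodes)
        valence = {n: g.nodes[n].get("valence", UNKNOWN) for n in nodes}
        edges: Set[Tuple[str, str, str]] = set()
        for a, b, data in g.edges(data=True):
            for layer in data.get("layer", SYNTACTIC).split("+"):
                edges.add((*_sorted_pair(a, b), layer))
        return TFMN(nodes=nodes, valence=valence, edges=edges)
    if format == "edgelist":
        edges = set()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            for line in fh:
                a, b, layer = line.rstrip("\n").split("\t")
                edges.add((*_sorted_pair(a, b), layer))
        nodes = {s for a, b, _ in edges for s in (a, b)}
        return TFMN(nodes=nodes, valence={n: UNKNOWN for n in nodes}, edges=edges)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            report = json.load(fh)
        validate_network_report(report)
        nodes = {n["id"] for n in report["nodes"]}
        valence = {n["id"]: n["valence"] for n in report["nodes"]}
        edges = {
            (*_sorted_pair(e["source"], e["target"]), e["layer"])
            for e in report["edges"]
        }
        return TFMN(nodes=nodes, valence=valence, edges=edges)
    raise ValueError(f"unknown import format {format!r}")


def _schema() -> dict:
    schema_path = Path(__file__).parent / "data" / "network_schema.json"
    with open(schema_path, encoding="utf-8") as fh:
        return json.load(fh)


def validate_network_report(report: dict) -> None:
    """Structural check of a JSON network report against the shipped schema."""
    schema = _schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"network report missing key {key!r}")
    node_req = schema["properties"]["nodes"]["items"]["required"]
    edge_req = schema["properties"]["edges"]["items"]["required"]
    valences = set(schema["properties"]["nodes"]["items"]["properties"]["valence"]["enum"])
    layers = set(schema["properties"]["edges"]["items"]["properties"]["layer"]["enum"])
    for n in report["nodes"]:
        if any(k not in n for k in node_req):
            raise ValueError(f"node entry missing keys: {n}")
        if n["valence"] not in valences:
            raise ValueError(f"bad valence {n['valence']!r}")
    ids = {n["id"] for n in report["nodes"]}
    for e in report["edges"]:
        if any(k not in e for k in edge_req):
            raise ValueError(f"edge entry missing keys: {e}")
        if e["layer"] not in layers:
            raise ValueError(f"bad layer {e['layer']!r}")
        if e["source"] not in ids or e["target"] not in ids:
            raise ValueError(f"edge references missing node: {e}")
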