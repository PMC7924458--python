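from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from formamentis.corpus import Document
from formamentis.lexicons import StemValenceTable, ValenceLabelMap, assign_valence_labels
from formamentis.metrics import (
    closeness,
    closeness_ranking,
    detect_communities,
    mean_clustering,
    null_clustering,
    rewire_configuration,
    shortest_path_distance,
    valence_aura,
    valence_class_comparison,
    valence_frequency_summary,
)
from formamentis.network import SYNTACTIC, TFMN


def _floyd_warshall(g):
    """Independent all-pairs oracle (no BFS)."""
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in g.edges:
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            for j in range(n):
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return nodes, idx, d


def _tfmn_from_graph(g, valence=None):
    edges = {(min(a, b), max(a, b), SYNTACTIC) for a, b in g.edges}
    nodes = set(g.nodes)
    valence = valence or {n: "neutral" for n in nodes}
    return TFMN(nodes=nodes, valence=valence, edges=edges)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def test_path_graph_distances():
    g = nx.path_graph(["a", "b", "c"])
    assert shortest_path_distance(g, "a", "c") == 2
    assert shortest_path_distance(g, "a", "a") == 0


def test_unreachable_pair_reports_none():
    g = nx.Graph()
    g.add_edge("a", "b")
    g.add_node("c")
    assert shortest_path_distance(g, "a", "c") is None


def test_absent_node_rejected():
    g = nx.path_graph(3)
    with pytest.raises(KeyError):
        shortest_path_distance(g, 0, 99)


def test_distances_match_floyd_warshall_on_random_graphs():
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(5, 31))
        g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31 - 1)))
        nodes, idx, d = _floyd_warshall(g)
        for _ in range(10):
            i, j = rng.choice(nodes, size=2)
            got = shortest_path_distance(g, int(i), int(j))
            want = d[idx[int(i)]][idx[int(j)]]
            assert (got is None) == (want == float("inf"))
            if got is not None:
                assert got == want


# ---------------------------------------------------------------------------
# Closeness (component-relative N / sum d)
# ---------------------------------------------------------------------------

def test_star_center_and_leaf_closeness():
    g = nx.star_graph(3)  # node 0 center, 4 nodes
    assert closeness(g, 0).exact == Fraction(4, 3)
    assert closeness(g, 1).exact == Fraction(4, 5)  # 4/(1+2+2)
    assert closeness(g, 1).value == pytest.approx(0.8)


def test_singleton_component_closeness_undefined():
    g = nx.Graph()
    g.add_node("x")
    s = closeness(g, "x")
    assert not s.defined
    assert np.isnan(s.value)


def test_conventional_variant_uses_n_minus_one():
    g = nx.star_graph(3)
    assert closeness(g, 0, conventional=True).exact == Fraction(3, 3)


def test_closeness_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(1)
    for trial in range(100):
        n = int(rng.integers(4, 31))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31 - 1)))
        nodes, idx, d = _floyd_warshall(g)
        i = int(rng.choice(nodes))
        comp = [j for j in nodes if d[idx[i]][idx[j]] != float("inf")]
        sum_d = sum(int(d[idx[i]][idx[j]]) for j in comp)
        s = closeness(g, i)
        assert s.component_size == len(comp)
        assert s.sum_distance == sum_d
        if sum_d > 0:
            assert s.exact == Fraction(len(comp), sum_d)


def test_ranking_star_center_first_and_k_truncation():
    g = nx.star_graph(4)
    ranked = closeness_ranking(g, k=1)
    assert ranked[0][0] == 0
    assert len(closeness_ranking(g, k=100)) == 5


def test_ranking_restricted_to_largest_component():
    g = nx.star_graph(4)
    g.add_edge("x", "y")  # small separate component
    ranked = closeness_ranking(g)
    assert {n for n, _ in ranked} == {0, 1, 2, 3, 4}


def test_ranking_matches_sorted_eq1_oracle(tfmn):
    from formamentis.network import aggregate_graph

    g = aggregate_graph(tfmn)
    giant = max(nx.connected_components(g), key=len)
    sub = g.subgraph(giant)
    oracle = sorted(
        ((n, closeness(sub, n).value) for n in sub.nodes),
        key=lambda t: (-t[1], t[0]),
    )
    assert closeness_ranking(tfmn) == oracle


def test_empty_graph_ranking_rejected():
    with pytest.raises(ValueError):
        closeness_ranking(nx.Graph())


# ---------------------------------------------------------------------------
# Valence auras
# ---------------------------------------------------------------------------

def _aura_tfmn(labels):
    """Star around 'hub' whose leaves carry the given labels."""
    leaves = {f"w{i}": lab for i, lab in enumerate(labels)}
    nodes = set(leaves) | {"hub"}
    valence = {**leaves, "hub": "neutral"}
    edges = {(min("hub", w), max("hub", w), SYNTACTIC) for w in leaves}
    return TFMN(nodes=nodes, valence=valence, edges=edges)


def test_two_of_five_positive_neighbours_is_fraction_point_four():
    tfmn = _aura_tfmn(["positive", "positive", "neutral", "negative", "neutral"])
    aura = valence_aura(tfmn, "hub")
    assert aura.fractions["positive"] == pytest.approx(0.4)
    assert sum(aura.fractions.values()) == pytest.approx(1.0)


def test_majority_positive_aura():
    tfmn = _aura_tfmn(["positive", "positive", "positive", "negative", "neutral"])
    assert valence_aura(tfmn, "hub").aura == "positive"


def test_tied_aura_is_mixed():
    tfmn = _aura_tfmn(["positive", "positive", "neutral", "neutral"])
    assert valence_aura(tfmn, "hub").aura == "mixed"


def test_unknown_neighbours_count_as_neutral():
    tfmn = _aura_tfmn(["unknown", "unknown", "positive"])
    aura = valence_aura(tfmn, "hub")
    assert aura.fractions["neutral"] == pytest.approx(2 / 3)


def test_isolated_focus_rejected():
    tfmn = TFMN(nodes={"a"}, valence={"a": "neutral"}, edges=set())
    with pytest.raises(ValueError):
        valence_aura(tfmn, "a")


def test_aura_argmax_consistency_across_fixture_nodes(tfmn):
    from formamentis.network import aggregate_graph

    g = aggregate_graph(tfmn)
    for n in tfmn.nodes:
        if g.degree(n) == 0:
            continue
        aura = valence_aura(tfmn, n)
        assert sum(aura.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        best = max(aura.fractions.values())
        winners = [l for l, f in aura.fractions.items() if f == best]
        assert aura.aura == (winners[0] if len(winners) == 1 else "mixed")


# ---------------------------------------------------------------------------
# Clustering and nulls
# ---------------------------------------------------------------------------

def test_triangle_clustering_is_one_and_path_is_zero():
    assert mean_clustering(nx.complete_graph(3)) == pytest.approx(1.0)
    assert mean_clustering(nx.path_graph(4)) == pytest.approx(0.0)


def test_k4_minus_one_edge_clustering():
    g = nx.complete_graph(4)
    g.remove_edge(0, 1)
    # hand count: degree-3 nodes have 2 of 3 closed triples, degree-2 nodes 1 of 1
    assert mean_clustering(g) == pytest.approx((1 + 2 / 3 + 2 / 3 + 1) / 4)


def test_rewiring_preserves_degree_sequence():
    g = nx.gnp_random_graph(25, 0.2, seed=4)
    for seed in range(20):
        r = rewire_configuration(g, seed=seed)
        assert sorted(dict(r.degree).values()) == sorted(dict(g.degree).values())
        assert r.number_of_edges() == g.number_of_edges()
        assert not any(a == b for a, b in r.edges)


def test_star_is_its_own_unique_realization():
    g = nx.star_graph(5)
    r = rewire_configuration(g, seed=0)
    assert set(map(frozenset, r.edges)) == set(map(frozenset, g.edges))


def test_rewiring_is_seed_deterministic():
    g = nx.gnp_random_graph(30, 0.15, seed=9)
    a = rewire_configuration(g, seed=77)
    b = rewire_configuration(g, seed=77)
    assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))


def test_null_clustering_of_triangle_is_degenerate():
    mean, sd = null_clustering(nx.complete_graph(3), realizations=5, seed=0)
    assert mean == pytest.approx(1.0)
    assert sd == pytest.approx(0.0)


def test_null_clustering_reproducible_and_below_planted_clustering():
    # graph with many planted triangles: connected caveman
    g = nx.connected_caveman_graph(6, 5)
    m1 = null_clustering(g, realizations=20, seed=3)
    m2 = null_clustering(g, realizations=20, seed=3)
    assert m1 == m2
    assert m1[0] < mean_clustering(g)


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def test_louvain_separates_two_bridged_cliques():
    g = nx.Graph()
    cl1 = [f"a{i}" for i in range(5)]
    cl2 = [f"b{i}" for i in range(5)]
    for grp in (cl1, cl2):
        g.add_edges_from((grp[i], grp[j]) for i in range(5) for j in range(i + 1, 5))
    g.add_edge(cl1[0], cl2[0])
    part = detect_communities(g, seed=0)
    assert len({part[n] for n in cl1}) == 1
    assert len({part[n] for n in cl2}) == 1
    assert part[cl1[0]] != part[cl2[0]]


def test_single_node_is_one_community():
    g = nx.Graph()
    g.add_node("x")
    assert detect_communities(g, seed=0) == {"x": 0}


def test_community_detection_is_seed_deterministic():
    g = nx.gnp_random_graph(40, 0.1, seed=12)
    assert detect_communities(g, seed=5) == detect_communities(g, seed=5)


# ---------------------------------------------------------------------------
# Valence class comparison
# ---------------------------------------------------------------------------

def test_planted_positive_clique_beats_negative_leaves():
    g = nx.Graph()
    pos = [f"p{i}" for i in range(8)]
    neg = [f"n{i}" for i in range(8)]
    g.add_edges_from((pos[i], pos[j]) for i in range(8) for j in range(i + 1, 8))
    for i, n in enumerate(neg):
        g.add_edge(pos[i], n)  # negatives are leaves
    valence = {**{p: "positive" for p in pos}, **{n: "negative" for n in neg}}
    tfmn = _tfmn_from_graph(g, valence)
    rep = valence_class_comparison(tfmn)
    assert rep.median_degree["positive"] > rep.median_degree["negative"]
    assert rep.degree_p < 0.05
    assert rep.median_closeness["positive"] > rep.median_closeness["negative"]


def test_empty_class_rejected():
    g = nx.path_graph(["a", "b"])
    tfmn = _tfmn_from_graph(g, {"a": "positive", "b": "neutral"})
    with pytest.raises(ValueError):
        valence_class_comparison(tfmn)


def test_swapping_labels_swaps_u_statistics():
    g = nx.Graph()
    pos = [f"p{i}" for i in range(5)]
    neg = [f"n{i}" for i in range(5)]
    g.add_edges_from((pos[i], pos[j]) for i in range(5) for j in range(i + 1, 5))
    for i, n in enumerate(neg):
        g.add_edge(pos[i], n)
    val1 = {**{p: "positive" for p in pos}, **{n: "negative" for n in neg}}
    val2 = {**{p: "negative" for p in pos}, **{n: "positive" for n in neg}}
    r1 = valence_class_comparison(_tfmn_from_graph(g, val1))
    r2 = valence_class_comparison(_tfmn_from_graph(g, val2))
    m, n_ = r1.n_positive, r1.n_negative
    assert r1.degree_u + r2.degree_u == pytest.approx(m * n_)


# ---------------------------------------------------------------------------
# Frequency summary
# ---------------------------------------------------------------------------

def _labelmap(**labels):
    return ValenceLabelMap(labels, q1=3.0, q3=7.0)


def test_token_and_type_counts_by_class():
    docs = [Document.from_raw("1", "good good bad")]
    lm = _labelmap(good="positive", bad="negative")
    summ = valence_frequency_summary(docs, lm)
    assert summ.type_counts["positive"] == 1
    assert summ.token_counts["positive"] == 2
    assert summ.type_counts["negative"] == 1
    assert summ.token_counts["negative"] == 1


def test_empty_corpus_counts_are_zero():
    lm = _labelmap(good="positive")
    summ = valence_frequency_summary([], lm)
    assert all(v == 0 for v in summ.type_counts.values())
    assert all(v == 0 for v in summ.token_counts.values())


def test_counts_match_brute_force_counter(parser, topic_corpus, bundle):
    from collections import Counter

    from formamentis.lexicons import stem_aggregate_valence
    from formamentis.stemming import stem

    docs = [d for ds in topic_corpus.documents_by_topic.values() for d in ds]
    lm = assign_valence_labels(stem_aggregate_valence(bundle.valence))
    summ = valence_frequency_summary(docs, lm, parser_backend=parser)

    counter = Counter()
    for d in docs:
        for s in d.sentences:
            dep = parser(s)
            for t in dep.tokens:
                if t.pos not in {"ADP", "AUX", "DET", "PART", "PUNCT", "CCONJ", "SCONJ", "SYM", "X"} or t.lemma in {"not", "n't", "nt"}:
                    counter[stem(t.lemma)] += 1
    for cls in ("positive", "negative", "neutral", "unknown"):
        stems = [s for s in counter if lm.label(s) == cls]
        assert summ.type_counts[cls] == len(stems)
        assert summ.token_counts[cls] == sum(counter[s] for s in stems)
        if summ.type_counts[cls] > 0:
            assert summ.token_counts[cls] >= summ.type_counts[cls]
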