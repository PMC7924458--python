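import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from formamentis.benchmark import (
    ReferenceNetwork,
    load_reference_network,
    mann_whitney_u,
    null_topic_distances,
    run_benchmark,
    topic_distances,
)
from formamentis.network import SYNTACTIC, TFMN


# ---------------------------------------------------------------------------
# Reference network and topic distances
# ---------------------------------------------------------------------------

def test_reference_distances_on_a_path():
    ref = ReferenceNetwork([("t", "a"), ("a", "b")])
    assert topic_distances(["a", "b"], ref, "t") == [1, 2]


def test_topic_itself_excluded_from_distances():
    ref = ReferenceNetwork([("t", "a")])
    assert topic_distances(["t", "a"], ref, "t") == [1]


def test_words_absent_from_reference_are_skipped(caplog):
    ref = ReferenceNetwork([("t", "a")])
    with caplog.at_level("INFO"):
        out = topic_distances(["a", "zzz"], ref, "t")
    assert out == [1]


def test_absent_topic_rejected():
    ref = ReferenceNetwork([("a", "b")])
    with pytest.raises(KeyError):
        topic_distances(["a"], ref, "t")


def test_reference_lookup_by_stem():
    ref = ReferenceNetwork([("weakness", "fear")])
    # "weak" resolves to the node "weakness" through shared stem
    assert ref.resolve("weak") == "weakness"
    assert ref.distance("weak", "fear") == 1


def test_distances_match_bfs_oracle():
    rng = np.random.default_rng(2)
    g = nx.gnp_random_graph(20, 0.15, seed=7)
    edges = [(f"w{a}", f"w{b}") for a, b in g.edges]
    ref = ReferenceNetwork(edges)
    topic = "w0"
    if ref.resolve(topic) is None:
        pytest.skip("isolated topic in random draw")
    words = [f"w{i}" for i in range(1, 20)]
    got = topic_distances(words, ref, topic)
    want = []
    for w in words:
        if w in ref.graph:
            try:
                want.append(nx.shortest_path_length(ref.graph, w, topic))
            except nx.NetworkXNoPath:
                pass
    assert got == want


def test_load_reference_network_tsv(tmp_path):
    p = tmp_path / "ref.tsv"
    p.write_text("# comment\nt\ta\na\tb\n", encoding="utf-8")
    ref = load_reference_network(p)
    assert ref.distance("b", "t") == 2


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------

def test_separated_samples_exact_p():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme


def test_identical_samples_p_is_one():
    u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_swapping_samples_maps_u_to_mn_minus_u():
    x, y = [1, 5, 7, 9], [2, 3, 8]
    u1, p1 = mann_whitney_u(x, y)
    u2, p2 = mann_whitney_u(y, x)
    assert u1 + u2 == pytest.approx(len(x) * len(y))
    assert p1 == pytest.approx(p2)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1])


def test_exact_enumeration_matches_scipy_on_tie_free_small_samples():
    """Full sweep over sample-size pairs with m+n <= 10, no ties."""
    rng = np.random.default_rng(6)
    for m in range(1, 6):
        for n in range(1, 6):
            if m + n > 10:
                continue
            vals = rng.permutation(np.arange(1, m + n + 1, dtype=float))
            x, y = list(vals[:m]), list(vals[m:])
            u, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_exact_enumeration_handles_ties_by_midranks():
    # with ties scipy's exact method is unavailable; check symmetry instead
    u, p = mann_whitney_u([1, 1, 2], [1, 2, 2])
    u2, _ = mann_whitney_u([1, 2, 2], [1, 1, 2])
    assert u + u2 == pytest.approx(9)
    assert 0 < p <= 1


def test_large_sample_branch_uses_normal_approximation():
    rng = np.random.default_rng(3)
    x = list(rng.normal(0, 1, 40))
    y = list(rng.normal(0.8, 1, 40))
    u, p = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue))


# ---------------------------------------------------------------------------
# Null distances and the full benchmark
# ---------------------------------------------------------------------------

def _star_tfmn(center, leaves):
    nodes = {center, *leaves}
    edges = {(min(center, l), max(center, l), SYNTACTIC) for l in leaves}
    return TFMN(nodes=nodes, valence={n: "neutral" for n in nodes}, edges=edges)


def test_unrewirable_star_null_equals_empirical():
    leaves = [f"leaf{i}" for i in range(4)]
    tfmn = _star_tfmn("topicword", leaves)
    ref = ReferenceNetwork([("topicword", l) for l in leaves])
    from formamentis.metrics import closeness_ranking

    ranked = [w for w, _ in closeness_ranking(tfmn, k=10)]
    empirical = topic_distances(ranked, ref, "topicword")
    null = null_topic_distances({"topicword": tfmn}, ref, k=10, realizations=1, seed=0)
    assert sorted(null) == sorted(empirical)


def test_null_distances_seed_deterministic(topic_corpus, bundle, parser):
    from formamentis.network import assemble_tfmn

    tfmns = {
        t: assemble_tfmn(list(docs), bundle, parser)
        for t, docs in topic_corpus.documents_by_topic.items()
    }
    ref = ReferenceNetwork(list(topic_corpus.reference_edges))
    a = null_topic_distances(tfmns, ref, realizations=3, seed=11)
    b = null_topic_distances(tfmns, ref, realizations=3, seed=11)
    assert a == b


def test_null_preserves_degree_sequences(topic_corpus, bundle, parser):
    from formamentis.metrics import rewire_configuration
    from formamentis.network import aggregate_graph, assemble_tfmn

    t = topic_corpus.topics[0]
    tfmn = assemble_tfmn(list(topic_corpus.documents_by_topic[t]), bundle, parser)
    g = aggregate_graph(tfmn)
    for seed in range(10):
        r = rewire_configuration(g, seed=seed)
        assert sorted(dict(r.degree).values()) == sorted(dict(g.degree).values())


def test_benchmark_on_planted_topics_is_significant(topic_corpus, bundle, parser):
    ref = ReferenceNetwork(list(topic_corpus.reference_edges))
    docs = {t: list(d) for t, d in topic_corpus.documents_by_topic.items()}
    res = run_benchmark(docs, ref, bundle, parser, realizations=20, seed=4)
    assert res.median_empirical < res.median_null
    assert res.p < 0.05
    assert res.significant


def test_adjacent_reference_gives_median_distance_one(topic_corpus, bundle, parser):
    """Reference wiring every document word next to its topic."""
    from formamentis.network import assemble_tfmn

    t = topic_corpus.topics[0]
    docs = {t: list(topic_corpus.documents_by_topic[t])}
    tfmn = assemble_tfmn(docs[t], bundle, parser)
    ref = ReferenceNetwork([(t, n) for n in tfmn.nodes if n != t])
    res = run_benchmark(docs, ref, bundle, parser, realizations=2, seed=0)
    assert res.median_empirical == 1


def test_zero_realizations_rejected(topic_corpus, bundle, parser):
    ref = ReferenceNetwork(list(topic_corpus.reference_edges))
    docs = {t: list(d) for t, d in topic_corpus.documents_by_topic.items()}
    with pytest.raises(ValueError):
        run_benchmark(docs, ref, bundle, parser, realizations=0, seed=0)


def test_unresolvable_topic_rejected(topic_corpus, bundle, parser):
    ref = ReferenceNetwork([("a", "b")])
    docs = {t: list(d) for t, d in topic_corpus.documents_by_topic.items()}
    with pytest.raises(KeyError):
        run_benchmark(docs, ref, bundle, parser, seed=0)
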