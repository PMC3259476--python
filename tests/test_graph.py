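"""Isotopic-cluster graph construction: arc colors, patterns, weights."""

import networkx as nx
import pytest

from deisograph.cluster_search import CandidateCluster
from deisograph.features import ClusterScorer
from deisograph.graph import (SINK, SOURCE, assign_weights, build_graph,
                              classify_pair)
from deisograph.spectrum import Peak
from tests.conftest import make_spectrum


def _cluster(indices, mzs, charge, intensities=None):
    if intensities is None:
        intensities = [10.0] * len(indices)
    peaks = tuple(Peak(mz=m, intensity=v, index=i)
                  for i, m, v in zip(indices, mzs, intensities))
    return CandidateCluster(peaks=peaks, charge=charge)


def _ladder(n, start=500.0, gap=1.003):
    return [start + k * gap for k in range(n)]


def test_rule_d_two_shared_peaks():
    mzs = _ladder(4)
    u = _cluster((0, 1, 2), mzs[:3], 1)
    v = _cluster((1, 2, 3), mzs[1:], 1)
    kind = classify_pair(u, v)
    assert kind is not None and (kind.color, kind.pattern) == ("red", "shared-d")
    assert classify_pair(v, u) is None  # head must start lower


def test_rule_c_one_shared_peak():
    mzs = _ladder(4)
    u = _cluster((0, 1, 2), mzs[:3], 1)
    v = _cluster((2, 3), mzs[2:], 1)
    kind = classify_pair(u, v)
    assert (kind.color, kind.pattern) == ("red", "shared-c")


def test_rule_b_two_peak_head():
    mzs = _ladder(3)
    u = _cluster((0, 1), mzs[:2], 1)
    v = _cluster((1, 2), mzs[1:], 1)
    kind = classify_pair(u, v)
    assert (kind.color, kind.pattern) == ("red", "shared-b")


def test_black_arc_disjoint_ranges():
    u = _cluster((0, 1), [500.0, 501.003], 1)
    v = _cluster((2, 3), [600.0, 601.003], 1)
    kind = classify_pair(u, v)
    assert (kind.color, kind.pattern) == ("black", "none")


def test_interleaved_red_arc_nested_only():
    mzs = [500.0 + k * 0.5015 for k in range(5)]
    outer = _cluster((0, 2, 4), [mzs[0], mzs[2], mzs[4]], 1)
    nested = _cluster((1, 3), [mzs[1], mzs[3]], 1)
    kind = classify_pair(outer, nested)
    assert (kind.color, kind.pattern) == ("red", "interleaved")
    # a no-share tail protruding beyond the head's span is not connected
    protruding = _cluster((2, 4), [mzs[2], mzs[4]], 1)
    assert classify_pair(nested, protruding) is None


def test_contained_tail_rejected():
    mzs = _ladder(3)
    u = _cluster((0, 1, 2), mzs, 1)
    v = _cluster((1, 2), mzs[1:], 1)
    assert classify_pair(u, v) is None


def test_unsanctioned_share_pattern_rejected():
    # heads sharing their own first peak with the tail are not connected
    mzs = _ladder(3)
    u = _cluster((0, 1), [mzs[0], mzs[1]], 1)
    v = _cluster((0, 2), [mzs[0], mzs[2]], 2)
    assert classify_pair(u, v) is None


def _bruteforce_kind(u, v):
    """Re-derivation of the red-arc rules from their textual statement."""
    ui, vi = u.member_indices, v.member_indices
    if vi[0] <= ui[0]:
        return None
    shared = set(ui) & set(vi)
    extends = bool(set(vi) - set(ui))
    if len(ui) == 2 and len(shared) >= 1 and ui[1] == vi[0] and extends:
        return "shared-b"
    if len(ui) == 3 and len(shared) == 1 and vi[0] in ui[1:] and extends:
        return "shared-c"
    if (len(ui) == 3 and len(shared) == 2 and ui[1] == vi[0]
            and ui[2] == vi[1] and extends):
        return "shared-d"
    return None


def test_red_patterns_match_bruteforce_classifier(rng):
    # every ordered pair of clusters over a short ladder
    mzs = [400.0 + k * 0.5015 for k in range(6)]
    from deisograph.cluster_search import find_peak_sets, enumerate_clusters
    sets, _ = find_peak_sets(make_spectrum(mzs))
    clusters = enumerate_clusters(sets[0])
    for u in clusters:
        for v in clusters:
            if u is v:
                continue
            kind = classify_pair(u, v)
            want = _bruteforce_kind(u, v)
            got = kind.pattern if kind and kind.pattern.startswith("shared") else None
            assert got == want, (u.member_indices, v.member_indices)


def _graph_for(mzs):
    from deisograph.cluster_search import find_peak_sets, enumerate_clusters
    spectrum = make_spectrum(mzs)
    sets, _ = find_peak_sets(spectrum)
    clusters = [c for ps in sets for c in enumerate_clusters(ps)]
    return spectrum, build_graph(clusters)


def test_graph_acyclic_and_connected(rng):
    for _ in range(20):
        n = int(rng.integers(3, 8))
        gap = float(rng.choice([1.003, 0.5015]))
        mzs = [500.0 + k * gap for k in range(n)]
        _, graph = _graph_for(mzs)
        assert graph.is_acyclic()
        for i in range(graph.n_clusters):
            assert nx.has_path(graph.g, SOURCE, i)
            assert nx.has_path(graph.g, i, SINK)


def test_sink_arcs_zero_weight_and_source_arcs_scored():
    spectrum, graph = _graph_for(_ladder(3))
    scorer = ClusterScorer(spectrum)
    assign_weights(graph, scorer.score)
    for u, v, data in graph.arcs():
        if v == SINK:
            assert data["weight"] == 0.0
        elif u == SOURCE:
            assert data["weight"] == pytest.approx(
                scorer.score(graph.cluster(v)))


def test_red_and_black_weights_differ_by_f5_correction():
    # same tail v reached via a shared-peak red arc and from the source:
    # only the red arc applies the overlap-corrected envelope criterion
    mzs = _ladder(4, start=900.0)
    spectrum = make_spectrum(mzs, intensities=[600.0, 700.0, 300.0, 80.0])
    from deisograph.cluster_search import find_peak_sets, enumerate_clusters
    sets, _ = find_peak_sets(spectrum)
    clusters = enumerate_clusters(sets[0])
    graph = build_graph(clusters)
    scorer = ClusterScorer(spectrum)
    assign_weights(graph, scorer.score)
    tail_node = next(i for i in range(graph.n_clusters)
                     if graph.cluster(i).member_indices == (1, 2, 3))
    weights = {}
    for u, v, data in graph.g.in_edges(tail_node, data=True):
        weights[data["kind"].pattern] = data["weight"]
    assert "shared-d" in weights and "none" in weights
    tail = graph.cluster(tail_node)
    head = next(c for c in clusters if c.member_indices == (0, 1, 2)
                and c.charge == 1)
    assert weights["shared-d"] == pytest.approx(scorer.score(tail, head))
    assert weights["none"] == pytest.approx(scorer.score(tail, None))


def test_scorer_failure_identifies_arc():
    _, graph = _graph_for(_ladder(3))

    def broken(cluster, partner=None):
        raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="arc"):
        assign_weights(graph, broken)
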