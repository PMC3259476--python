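"""Isotopic-cluster graphs: overlap-aware DAGs over candidate clusters.

One graph is built per isotopic peak set.  Vertices are the set's
candidate clusters plus a source and a sink.  Arcs run from a *head*
cluster to a *tail* cluster whose first peak has strictly greater m/z:

* **black** arcs connect clusters with disjoint peak-index ranges (the
  tail starts after the head ends) — no overlap;
* **red** arcs connect overlapping clusters, in one of the sanctioned
  patterns:

  - ``shared-b``: 2-peak head whose second peak is the tail's first;
  - ``shared-c``: 3-peak head sharing exactly one peak, at the tail's
    first position;
  - ``shared-d``: 3-peak head whose second and third peaks are the tail's
    first and second;
  - ``interleaved``: index ranges overlap but no peak is shared (two
    envelopes threaded through each other).

A red arc additionally requires the tail to own at least one peak outside
the head: a cluster whose peaks are a subset of another's is the same ion
hypothesis, not a second overlapping fragment.

Arc weights carry the score of the arc's *tail* cluster, evaluated under
the overlap relationship the arc asserts, so that a path's total weight
is the sum of its clusters' scores; arcs into the sink weigh zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx

from .cluster_search import CandidateCluster

__all__ = ["ArcKind", "ClusterGraph", "build_graph", "assign_weights", "classify_pair"]

SOURCE = "source"
SINK = "sink"


@dataclass(frozen=True)
class ArcKind:
    """Label of an arc: its color and overlap pattern."""

    color: str           # "red" or "black"
    pattern: str         # "none", "shared-b", "shared-c", "shared-d", "interleaved"


BLACK = ArcKind("black", "none")


def classify_pair(u: CandidateCluster, v: CandidateCluster) -> ArcKind | None:
    """Arc label for the ordered cluster pair (head u, tail v), or None.

    Requires v's first peak to sit at strictly greater m/z (index) than
    u's first peak; otherwise no arc exists in this direction.
    """
    ui, vi = u.member_indices, v.member_indices
    if vi[0] <= ui[0]:
        return None
    shared = set(ui) & set(vi)
    if not shared:
        if vi[0] > ui[-1]:
            return BLACK
        if vi[-1] < ui[-1]:
            # tail nested inside the head's span with no shared peak:
            # interleaved envelopes threaded through each other
            return ArcKind("red", "interleaved")
        return None
    if not (set(vi) - set(ui)):
        return None  # tail contained in head: same ion hypothesis
    if len(ui) == 2 and ui[1] == vi[0]:
        return ArcKind("red", "shared-b")
    if len(ui) == 3 and len(shared) == 1 and vi[0] in (ui[1], ui[2]):
        return ArcKind("red", "shared-c")
    if len(ui) == 3 and len(shared) == 2 and ui[1] == vi[0] and ui[2] == vi[1]:
        return ArcKind("red", "shared-d")
    return None


class ClusterGraph:
    """A DAG over the candidate clusters of one peak set."""

    def __init__(self, clusters: Iterable[CandidateCluster]) -> None:
        self.clusters: list[CandidateCluster] = sorted(
            clusters, key=lambda c: (c.member_indices[0], c.member_indices, c.charge))
        self.g = nx.DiGraph()
        self.g.add_node(SOURCE)
        self.g.add_node(SINK)
        for i in range(len(self.clusters)):
            self.g.add_node(i)

    def cluster(self, node: int) -> CandidateCluster:
        return self.clusters[node]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def arcs(self):
        return self.g.edges(data=True)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.g)

    def to_dot(self) -> str:
        """DOT rendering for debugging (red/black edges, score labels)."""
        lines = ["digraph clusters {"]
        for i, c in enumerate(self.clusters):
            mzs = ",".join(f"{p.mz:.4f}" for p in c.peaks)
            lines.append(f'  n{i} [label="[{mzs}] z={c.charge}"];')
        for u, v, data in self.g.edges(data=True):
            kind: ArcKind = data.get("kind", BLACK)
            w = data.get("weight", 0.0)
            su = "source" if u == SOURCE else f"n{u}"
            sv = "sink" if v == SINK else f"n{v}"
            lines.append(f'  {su} -> {sv} [color={kind.color} label="{w:.3f}"];')
        lines.append("}")
        return "\n".join(lines)


def build_graph(clusters: Iterable[CandidateCluster]) -> ClusterGraph:
    """Construct the isotopic-cluster DAG for one peak set.

    The source and sink connect to every cluster, so a path may begin and
    end at any cluster.  Since cluster scores are non-negative this leaves
    the maximum path score unchanged relative to attaching only terminal
    clusters, while letting the tie-break drop zero-score head and tail
    clusters that a forced continuation would otherwise sweep in.
    """
    graph = ClusterGraph(clusters)
    n = graph.n_clusters
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            kind = classify_pair(graph.clusters[i], graph.clusters[j])
            if kind is not None:
                graph.g.add_edge(i, j, kind=kind, weight=0.0)
    for i in range(n):
        graph.g.add_edge(SOURCE, i, kind=BLACK, weight=0.0)
        graph.g.add_edge(i, SINK, kind=BLACK, weight=0.0)
    return graph


def assign_weights(
    graph: ClusterGraph,
    scorer: Callable[[CandidateCluster, CandidateCluster | None], float],
) -> ClusterGraph:
    """Attach scores to arcs.

    ``scorer(cluster, partner)`` returns the score of ``cluster`` under
    the overlap relationship with ``partner`` (None for no overlap).  The
    weight of an arc u -> v is the score of v: red shared-peak arcs score
    v against u (the F5 overlap correction applies), black and
    interleaved arcs score v in isolation; sink arcs weigh zero.
    """
    for u, v, data in graph.g.edges(data=True):
        if v == SINK:
            data["weight"] = 0.0
            continue
        tail = graph.cluster(v)
        kind: ArcKind = data["kind"]
        partner = None
        if u != SOURCE and kind.color == "red" and kind.pattern.startswith("shared"):
            partner = graph.cluster(u)
        try:
            data["weight"] = float(scorer(tail, partner))
        except Exception as exc:
            raise RuntimeError(
                f"scorer failed on arc {u}->{v} (tail {tail.member_indices}, "
                f"pattern {kind.pattern})") from exc
    return graph
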