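"""Highest-score path search in isotopic-cluster graphs.

The graph is a DAG, so the maximum-weight source-to-sink path is found by
dynamic programming over a topological order in time linear in the number
of arcs.  Ties are broken deterministically: among equal-score paths the
one with fewer clusters wins, then the lexicographically smallest
sequence of first-member m/z values.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .cluster_search import CandidateCluster
from .graph import SINK, SOURCE, ClusterGraph
from .spectrum import DeisotopedIon, Spectrum, sorted_ions

__all__ = ["PathResult", "highest_score_path", "select_ions"]

#: Scores closer than this are treated as equal when breaking path ties.
_SCORE_TOL = 1e-9


@dataclass(frozen=True)
class PathResult:
    """The selected arrangement of clusters for one peak set."""

    clusters: tuple[CandidateCluster, ...]
    total_score: float
    per_arc: tuple[tuple[str, float], ...]  # (pattern, weight) per traversed arc


def _path_key(graph: ClusterGraph, nodes: list) -> tuple[float, ...]:
    return tuple(graph.cluster(n).mono_mz for n in nodes if n not in (SOURCE, SINK))


def highest_score_path(graph: ClusterGraph) -> PathResult:
    """Maximum-total-weight source-to-sink path by DP over topological order.

    Raises if the graph contains no source-to-sink path (a peak set with
    no candidate cluster never produces a graph, so this indicates a
    malformed graph).
    """
    order = list(nx.topological_sort(graph.g))
    best: dict[object, tuple[float, int, tuple[float, ...], list]] = {
        SOURCE: (0.0, 0, (), [SOURCE])
    }
    for node in order:
        if node not in best:
            continue
        score, length, key, path = best[node]
        for _, v, data in graph.g.out_edges(node, data=True):
            w = data.get("weight", 0.0)
            cand_key = key if v == SINK else key + (graph.cluster(v).mono_mz,)
            cand = (score + w, length + (0 if v == SINK else 1), cand_key, path + [v])
            if v not in best:
                best[v] = cand
                continue
            cur = best[v]
            # higher score, then fewer clusters, then smaller m/z sequence;
            # scores within a round-off tolerance count as tied
            delta = cand[0] - cur[0]
            if delta > _SCORE_TOL:
                best[v] = cand
            elif delta >= -_SCORE_TOL and (cand[1], cand[2]) < (cur[1], cur[2]):
                best[v] = cand
    if SINK not in best:
        raise ValueError("graph has no source-to-sink path")
    score, _, _, path = best[SINK]
    clusters = tuple(graph.cluster(n) for n in path if n not in (SOURCE, SINK))
    per_arc = []
    for a, b in zip(path, path[1:]):
        data = graph.g.edges[a, b]
        per_arc.append((data["kind"].pattern, data.get("weight", 0.0)))
    return PathResult(clusters=clusters, total_score=score, per_arc=tuple(per_arc))


def select_ions(
    spectrum: Spectrum,
    path_results: list[PathResult],
    keep_singletons: bool = True,
    intensity_split: str = "full",
    cluster_scores: dict[tuple[tuple[int, ...], int], float] | None = None,
) -> list[DeisotopedIon]:
    """Assemble the output ion list from the per-set optimal paths.

    One ion per selected cluster (monoisotopic m/z = first member, charge
    = cluster charge, intensity = summed member intensities).  Peaks
    claimed by no selected cluster are emitted as charge-1 single-peak
    ions when ``keep_singletons`` is set.

    ``intensity_split="proportional"`` divides a peak claimed by several
    clusters equally between the claimants; the default ``"full"``
    credits it fully to every claimant.
    """
    selected = [c for result in path_results for c in result.clusters]
    claim_count: dict[int, int] = {}
    for cluster in selected:
        for idx in cluster.member_indices:
            claim_count[idx] = claim_count.get(idx, 0) + 1
    ions: list[DeisotopedIon] = []
    for cluster in selected:
        if intensity_split == "proportional":
            intensity = sum(p.intensity / claim_count[p.index] for p in cluster.peaks)
        elif intensity_split == "full":
            intensity = cluster.summed_intensity
        else:
            raise ValueError(f"unknown intensity split {intensity_split!r}")
        score = 0.0
        if cluster_scores is not None:
            score = cluster_scores.get((cluster.member_indices, cluster.charge), 0.0)
        ions.append(DeisotopedIon(
            mono_mz=cluster.mono_mz,
            charge=cluster.charge,
            intensity=intensity,
            member_indices=cluster.member_indices,
            score=score,
        ))
    if keep_singletons:
        claimed = set(claim_count)
        for peak in spectrum.peaks:
            if peak.index not in claimed:
                ions.append(DeisotopedIon(
                    mono_mz=peak.mz, charge=1, intensity=peak.intensity,
                    member_indices=(peak.index,),
                ))
    return sorted_ions(ions)
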