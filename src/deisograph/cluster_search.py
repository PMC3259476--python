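"""Enumeration of isotopic peak sets and candidate isotopic clusters.

The search runs in two passes over an m/z-sorted spectrum:

1. **Peak sets** — maximal chains of peaks in which every consecutive pair
   is separated by ``1.003 / z`` for *some* charge ``z`` (charges may mix
   along the chain, as interleaved envelopes of different charge states
   produce exactly such mixed spacings).  Chaining is greedy from the
   lowest-m/z unassigned peak; every peak belongs to at most one set, and
   peaks in no set are reported as singletons.

2. **Candidate clusters** — within each set, every sub-sequence of 2 or 3
   peaks (members need not be adjacent in the set, so interleaved
   envelopes are found) whose consecutive internal gaps all match
   ``1.003 / z`` for one common charge ``z`` within the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .constants import ISOTOPE_GAP
from .spectrum import Peak, Spectrum

__all__ = [
    "SearchParams",
    "IsotopicPeakSet",
    "CandidateCluster",
    "find_peak_sets",
    "enumerate_clusters",
]


@dataclass(frozen=True)
class SearchParams:
    """Spacing rules of the cluster search.

    ``iso_gap`` is the average spacing between adjacent isotope peaks of a
    1+ ion (Da); ``gap_tolerance`` is an absolute m/z window around each
    admissible spacing.
    """

    iso_gap: float = ISOTOPE_GAP
    gap_tolerance: float = 0.01
    charges: frozenset[int] = frozenset({1, 2, 3})
    max_cluster_len: int = 3
    min_cluster_len: int = 2

    def __post_init__(self) -> None:
        if not self.iso_gap > 0:
            raise ValueError("iso_gap must be positive")
        if not self.gap_tolerance > 0:
            raise ValueError("gap_tolerance must be positive")
        if not self.charges:
            raise ValueError("charges must be nonempty")
        if self.min_cluster_len < 2 or self.max_cluster_len < self.min_cluster_len:
            raise ValueError("cluster length bounds must satisfy 2 <= min <= max")

    def gap_charge(self, gap: float) -> int | None:
        """The smallest charge whose spacing matches ``gap``, or None."""
        for z in sorted(self.charges):
            if abs(gap - self.iso_gap / z) <= self.gap_tolerance:
                return z
        return None

    def matches_charge(self, gap: float, z: int) -> bool:
        return abs(gap - self.iso_gap / z) <= self.gap_tolerance


DEFAULT_SEARCH_PARAMS = SearchParams()


@dataclass(frozen=True)
class IsotopicPeakSet:
    """A maximal chain of peaks linked by admissible isotopic gaps."""

    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) < 2:
            raise ValueError("a peak set needs at least 2 peaks")

    @property
    def start_index(self) -> int:
        return self.peaks[0].index

    @property
    def end_index(self) -> int:
        return self.peaks[-1].index

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CandidateCluster:
    """A charge-annotated run of 2-3 peaks hypothesized to be one envelope."""

    peaks: tuple[Peak, ...]
    charge: int

    def __post_init__(self) -> None:
        if not 2 <= len(self.peaks) <= 3:
            raise ValueError("clusters have 2 or 3 peaks")
        if self.charge < 1:
            raise ValueError("cluster charge must be >= 1")

    @property
    def member_indices(self) -> tuple[int, ...]:
        return tuple(p.index for p in self.peaks)

    @property
    def mono_mz(self) -> float:
        return self.peaks[0].mz

    @property
    def summed_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)

    @property
    def neutral_mass(self) -> float:
        """Neutral-mass estimate used to look up the theoretical envelope."""
        from .constants import M_H
        return (self.mono_mz - M_H) * self.charge

    def __len__(self) -> int:
        return len(self.peaks)


def find_peak_sets(
    spectrum: Spectrum,
    params: SearchParams = DEFAULT_SEARCH_PARAMS,
) -> tuple[list[IsotopicPeakSet], list[Peak]]:
    """Partition a spectrum into maximal isotopic peak sets and singletons.

    Starting from the lowest-m/z unassigned peak, the chain is extended by
    the nearest unassigned peak whose gap to the current chain end matches
    ``iso_gap / z`` for any admissible charge.  Chains of length >= 2
    become sets; all remaining peaks are returned as singletons.
    """
    unassigned = list(spectrum.peaks)
    sets: list[IsotopicPeakSet] = []
    singletons: list[Peak] = []
    max_gap = params.iso_gap / min(params.charges) + params.gap_tolerance
    while unassigned:
        chain = [unassigned.pop(0)]
        while True:
            last = chain[-1]
            extension = None
            for peak in unassigned:
                gap = peak.mz - last.mz
                if gap > max_gap:
                    break
                if params.gap_charge(gap) is not None:
                    extension = peak
                    break
            if extension is None:
                break
            chain.append(extension)
            unassigned.remove(extension)
        if len(chain) >= 2:
            sets.append(IsotopicPeakSet(peaks=tuple(chain)))
        else:
            singletons.append(chain[0])
    return sets, singletons


def enumerate_clusters(
    peak_set: IsotopicPeakSet,
    params: SearchParams = DEFAULT_SEARCH_PARAMS,
) -> list[CandidateCluster]:
    """All candidate isotopic clusters inside one peak set.

    Every 2- or 3-subset of the set's peaks qualifies if its consecutive
    internal gaps all match ``iso_gap / z`` for one common charge z within
    the tolerance (members may skip over interleaved peaks of the set).
    Clusters are returned sorted by (first-peak m/z, charge, length) and
    deduplicated.
    """
    clusters: list[CandidateCluster] = []
    seen: set[tuple[tuple[int, ...], int]] = set()
    peaks = peak_set.peaks
    for size in range(params.min_cluster_len, params.max_cluster_len + 1):
        for combo in combinations(peaks, size):
            gaps = [b.mz - a.mz for a, b in zip(combo, combo[1:])]
            for z in sorted(params.charges):
                if all(params.matches_charge(g, z) for g in gaps):
                    key = (tuple(p.index for p in combo), z)
                    if key not in seen:
                        seen.add(key)
                        clusters.append(CandidateCluster(peaks=combo, charge=z))
    clusters.sort(key=lambda c: (c.mono_mz, c.charge, len(c)))
    return clusters
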