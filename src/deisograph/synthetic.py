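"""Synthetic tandem spectra with planted, ground-truthed isotopic clusters.

The generator emulates the signal structure the deisotoping stages rely
on, without any instrument data:

* **planted clusters** — 2- or 3-peak envelopes at exact ``1.003/z``
  spacings whose intensities follow the averagine mean envelope at the
  cluster's mass;
* **decoration peaks** — partner peaks placed at exact feature-clause
  targets (complementary fragments, neutral-loss satellites, residue
  ladder partners), so true clusters accumulate feature support the way
  real CID fragments do;
* **noise peaks** — low-intensity peaks at random m/z.

Two collision screens keep the planted ground truth unambiguous: no
generated peak may fall within a small window of a position that would
extend an isotopic chain of any existing peak, and decoration peaks are
additionally rejected if they would satisfy a feature clause for any
envelope peak other than the one they are planted for.  Overlap
archetypes (interleaved envelopes and the three shared-peak patterns)
are constructed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, ISOTOPE_GAP, M_H, MassConstants
from .features import DEFAULT_FEATURE_PARAMS, FeatureParams
from .isotope_model import AVERAGINE_MODEL, elemental_distribution
from .spectrum import DeisotopedIon, Spectrum

__all__ = [
    "PlantedCluster",
    "SyntheticSpec",
    "generate",
    "complement_decorate",
    "overlap_archetype",
    "RecoveryMetrics",
    "planted_recovery",
    "ARCHETYPES",
]


@dataclass(frozen=True)
class PlantedCluster:
    """Ground truth for one planted isotopic envelope."""

    mono_mz: float
    charge: int
    n_peaks: int
    intensity_scale: float = 1000.0
    envelope: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 2 <= self.n_peaks <= 3:
            raise ValueError("planted clusters have 2 or 3 peaks")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def member_mzs(self) -> tuple[float, ...]:
        return tuple(self.mono_mz + k * ISOTOPE_GAP / self.charge
                     for k in range(self.n_peaks))

    @property
    def neutral_mass(self) -> float:
        return (self.mono_mz - M_H) * self.charge

    def intensities(self) -> tuple[float, ...]:
        env = self.envelope
        if not env:
            d = elemental_distribution(
                AVERAGINE_MODEL.formula_for_mass(self.neutral_mass),
                n_isotopes=self.n_peaks)
            env = tuple(d / d.sum())
        return tuple(self.intensity_scale * v for v in env)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic spectrum.

    If ``clusters`` is empty, ``n_clusters`` envelopes are sampled:
    monoisotopic positions uniform in ``mz_range`` with at least
    ``min_separation`` between them (so envelopes and their ladders stay
    distinguishable), charges drawn from ``charge_weights``, and 3-peak
    envelopes for ions above ``three_peak_mass`` (lighter ions' +2
    isotope would sit below a realistic detection floor).

    Noise peaks number ``noise_fraction`` times the planted envelope
    peaks, with log-uniform intensities between 1% and 30% of the median
    planted base-peak intensity.  ``mz_jitter`` is the standard deviation
    of Gaussian m/z error applied to every peak.
    """

    seed: int = 0
    clusters: tuple[PlantedCluster, ...] = ()
    n_clusters: int = 6
    mz_range: tuple[float, float] = (200.0, 1400.0)
    min_separation: float = 190.0
    charge_weights: tuple[tuple[int, float], ...] = ((1, 0.55), (2, 0.35), (3, 0.10))
    three_peak_mass: float = 900.0
    noise_fraction: float = 0.3
    mz_jitter: float = 0.003
    precursor_neutral_mass: float = 1800.0
    precursor_charge: int = 2
    decorate: bool = True
    n_complements: int = 2
    satellites: bool = True
    residue_partners: bool = True
    collision_window: float = 0.012

    def clean(self) -> "SyntheticSpec":
        """The noiseless, jitterless variant of this recipe."""
        return replace(self, noise_fraction=0.0, mz_jitter=0.0)


def _admissible_gaps(charges: Iterable[int] = (1, 2, 3)) -> list[float]:
    return [ISOTOPE_GAP / z for z in charges]


def _extends_chain(q: float, existing: Sequence[float], window: float) -> bool:
    """Would a peak at q form an isotopic gap with any existing peak?"""
    for p in existing:
        d = abs(q - p)
        for gap in _admissible_gaps():
            if abs(d - gap) <= window:
                return True
    return False


def _fires_diff_clauses(x: float, q: float, targets: Sequence[float],
                        theta: float, m_h: float) -> bool:
    d = x - q
    exprs = (
        (abs(d), 1), (abs(d), 2), (abs(d), 3),
        (abs(d + m_h / 2), 2), (abs(-d + m_h / 2), 2),
        (abs(d + 2 * m_h / 3), 3), (abs(-d + 2 * m_h / 3), 3),
        (abs(x - 2 * q + m_h / 3), 3), (abs(q - 2 * x + m_h / 3), 3),
    )
    for expr, div in exprs:
        for t in targets:
            if abs(expr - t / div) <= theta:
                return True
    return False


def _fires_sum_clauses(x: float, q: float, M: float, i: int,
                       params: FeatureParams, m_h: float) -> bool:
    base = M + params.f2_offset(i)
    t1, t2, t3 = base + 2 * m_h, base / 2 + 2 * m_h, base / 3 + 2 * m_h
    s1 = x + q
    exprs = (
        (s1, t1), (s1, t2), (s1, t3),
        (s1 + m_h / 2, t2),
        (s1 + 2 * m_h / 3, t3),
        (x + 2 * q + m_h / 3, t3),
        (q + 2 * x + m_h / 3, t3),
    )
    return any(abs(expr - t) <= params.theta for expr, t in exprs)


def _diff_targets(consts: MassConstants) -> list[float]:
    targets = sorted(set(consts.residue_masses.values()))
    targets += [consts.M_H2O, consts.M_NH3, consts.M_CO, consts.M_NH]
    return targets


def _harmful_peaks(truth: Sequence[PlantedCluster], window: float = 0.02) -> set[float]:
    """Envelope peaks whose *extra* feature support could flip the DP.

    Planted peaks are grouped into isotopic chains (runs linked by
    admissible gaps).  In a chain hosting a single cluster, only the
    interior peaks can gain multiplicity in a competitor tiling (a split
    counts the middle twice), so only they need clause silence.  In a
    chain hosting several clusters — the overlap configurations — any
    peak can be re-claimed through a shared-peak or interleave arc, so
    every peak of the chain is treated as critical.
    """
    owners: dict[float, set[int]] = {}
    for ci, cluster in enumerate(truth):
        for mz in cluster.member_mzs:
            owners.setdefault(round(mz, 4), set()).add(ci)
    positions = sorted(owners)
    gaps = _admissible_gaps()

    def linked(a: float, b: float) -> bool:
        return any(abs((b - a) - g) <= window for g in gaps)

    harmful: set[float] = set()
    chain: list[float] = []
    for k, mz in enumerate(positions):
        chain.append(mz)
        end = k + 1 == len(positions) or not linked(mz, positions[k + 1])
        if end:
            clusters_here = set().union(*(owners[p] for p in chain))
            if len(clusters_here) > 1:
                harmful.update(chain)
            else:
                harmful.update(chain[1:-1])
            chain = []
    return harmful


def _feature_silent(
    q: float,
    envelope_positions: Sequence[tuple[float, tuple[tuple[int, int], ...]]],
    M: float,
    allowed: set[tuple[float, int]],
    consts: MassConstants,
    params: FeatureParams,
    harmful: set[float] | None = None,
    safety: float = 0.02,
) -> bool:
    """True if a peak at q fires no distorting feature clause.

    ``envelope_positions`` maps each envelope peak m/z to the (cluster id,
    position) pairs it occupies; ``allowed`` contains the (peak m/z,
    position) combinations the decoration is designed to support.
    Difference clauses (F1/F3/F4) are screened against the ``harmful``
    peaks (all envelope peaks when None); complementarity clauses (F2)
    are screened against every envelope peak at every cluster position,
    because position-shifted complementarity support props up competitor
    tilings.
    """
    theta = params.theta + safety
    diff_targets = _diff_targets(consts)
    for x, occupancies in envelope_positions:
        diff_screened = harmful is None or x in harmful
        if diff_screened and (x, -1) not in allowed:
            if _fires_diff_clauses(x, q, diff_targets, theta, consts.M_H):
                return False
        positions = {pos for _, pos in occupancies} | {0, 1, 2}
        for i in positions:
            if (x, i) in allowed:
                continue
            if _fires_sum_clauses(x, q, M, i,
                                  replace(params, theta=theta), consts.M_H):
                return False
    return True


def _complement_candidates(x: float, i: int, M: float,
                           params: FeatureParams, m_h: float) -> list[float]:
    """Positions at which a complement peak of (x, position i) may lie.

    One exact position per clause family, then off-center variants still
    inside each clause's ±θ window: a real complementary fragment matches
    within the tolerance rather than exactly, and the slack lets the
    generator dodge clause windows of unrelated peaks.
    """
    base = M + params.f2_offset(i)
    t1, t2, t3 = base + 2 * m_h, base / 2 + 2 * m_h, base / 3 + 2 * m_h
    exact = [
        t1 - x,                      # sum1 against full-mass target
        t2 - x - m_h / 2,            # sum2 against half-mass target
        t2 - x,                      # sum1 against half-mass target
        t3 - x - 2 * m_h / 3,        # sum3 against third-mass target
        t3 - x,                      # sum1 against third-mass target
        (t3 - x - m_h / 3) / 2,      # sum4(x, y); window scales by 1/2
        t3 - 2 * x - m_h / 3,        # sum4(y, x)
    ]
    scale = [1.0, 1.0, 1.0, 1.0, 1.0, 0.5, 1.0]  # y enters sum4(x,y) doubled
    candidates = list(exact)
    for offset in (-0.2, 0.2, -0.12, 0.12):
        candidates.extend(q + offset * s for q, s in zip(exact, scale))
    return candidates


def _merge_peaks(positions: Sequence[float], intensities: Sequence[float],
                 tol: float = 1e-4) -> tuple[list[float], list[float]]:
    """Sum intensities of coincident positions (shared envelope peaks)."""
    order = np.argsort(positions)
    out_mz: list[float] = []
    out_int: list[float] = []
    for k in order:
        if out_mz and abs(positions[k] - out_mz[-1]) <= tol:
            out_int[-1] += intensities[k]
        else:
            out_mz.append(positions[k])
            out_int.append(intensities[k])
    return out_mz, out_int


def _cluster_occupancies(
    truth: Sequence[PlantedCluster],
) -> list[tuple[float, tuple[tuple[int, int], ...]]]:
    by_mz: dict[float, list[tuple[int, int]]] = {}
    for ci, cluster in enumerate(truth):
        for pos, mz in enumerate(cluster.member_mzs):
            by_mz.setdefault(round(mz, 4), []).append((ci, pos))
    return [(mz, tuple(occ)) for mz, occ in sorted(by_mz.items())]


def complement_decorate(
    spectrum: Spectrum,
    truth: Sequence[PlantedCluster],
    M: float | None = None,
    n_complements: int = 2,
    satellites: bool = True,
    residue_partners: bool = True,
    consts: MassConstants = DEFAULT_CONSTANTS,
    params: FeatureParams = DEFAULT_FEATURE_PARAMS,
    collision_window: float = 0.012,
) -> Spectrum:
    """Add feature-supporting partner peaks for the planted clusters.

    For every member of every true cluster, up to ``n_complements``
    complementary peaks are planted at exact F2 clause targets for the
    member's position; the monoisotopic member additionally receives
    neutral-loss (F3), supportive-ion (F4) and, optionally, residue-ladder
    (F1) partners.  A candidate partner position is skipped if it would
    extend an isotopic chain of any existing peak or satisfy a feature
    clause for an envelope peak it is not designed for, so the decoration
    raises the scores of true clusters and of nothing else.
    """
    if M is None:
        M = spectrum.precursor_neutral_mass
    occupancies = _cluster_occupancies(truth)
    harmful = _harmful_peaks(truth)
    # complementarity support at any *planted* (peak, position) assignment
    # reinforces the true arrangement and is never screened out
    truth_positions = {(mz, pos) for mz, occ in occupancies for _, pos in occ}
    mzs = list(spectrum.mz_array)
    intensities = list(spectrum.intensity_array)
    median_intensity = float(np.median(intensities)) if intensities else 1.0

    def try_add(candidates: Iterable[float], allowed: set[tuple[float, int]],
                limit: int) -> int:
        added = 0
        for q in candidates:
            if added >= limit:
                break
            if q <= 50.0:
                continue
            if _extends_chain(q, mzs, collision_window):
                continue
            if not _feature_silent(q, occupancies, M, allowed, consts, params,
                                   harmful=harmful):
                continue
            mzs.append(q)
            intensities.append(0.5 * median_intensity)
            added += 1
        return added

    residue_order = ["A", "G", "V", "L", "S", "E", "F", "R", "D", "K"]
    for cluster in truth:
        members = cluster.member_mzs
        for i, x in enumerate(members):
            xk = round(x, 4)
            try_add(
                _complement_candidates(x, i, M, params, consts.M_H),
                allowed=truth_positions | {(xk, i)},
                limit=n_complements,
            )
        mono = round(members[0], 4)
        if mono in harmful:
            # a mono inside a longer chain would have its satellite and
            # ladder support double-counted by competitor tilings
            continue
        if satellites:
            try_add([members[0] - consts.M_H2O, members[0] - consts.M_NH3],
                    allowed=truth_positions | {(mono, -1)}, limit=1)
            try_add([members[0] - consts.M_CO, members[0] - consts.M_NH],
                    allowed=truth_positions | {(mono, -1)}, limit=1)
        if residue_partners:
            try_add([members[0] + consts.residue_masses[r] for r in residue_order],
                    allowed=truth_positions | {(mono, -1)}, limit=1)
    return Spectrum.from_arrays(
        mzs, intensities, spectrum.precursor_mz, spectrum.precursor_charge,
        title=spectrum.title)


def _layout_silent(clusters: Sequence[PlantedCluster], M: float,
                   consts: MassConstants = DEFAULT_CONSTANTS,
                   params: FeatureParams = DEFAULT_FEATURE_PARAMS,
                   safety: float = 0.02) -> bool:
    """True if no planted envelope peak fires a clause for another cluster.

    Within-cluster pairs are exempt (isotopic spacings are fixed and far
    from every clause target); cross-cluster pairs must stay silent so the
    planted arrangement alone determines the feature support — mirroring
    well-separated fragment ladders.
    """
    theta = params.theta + safety
    diff_targets = _diff_targets(consts)
    loose = replace(params, theta=theta)
    for a in clusters:
        for b in clusters:
            if a is b:
                continue
            for x in a.member_mzs:
                for q in b.member_mzs:
                    if abs(x - q) < 1e-6:
                        continue  # shared peak of overlapping envelopes
                    if _fires_diff_clauses(x, q, diff_targets, theta, consts.M_H):
                        return False
                    if any(_fires_sum_clauses(x, q, M, i_x, loose, consts.M_H)
                           for i_x in range(3)):
                        return False
    return True


def _sample_clusters(spec: SyntheticSpec, rng: np.random.Generator) -> list[PlantedCluster]:
    lo, hi = spec.mz_range
    n = spec.n_clusters
    slack = (hi - lo) - (n - 1) * spec.min_separation
    if slack <= 0:
        raise ValueError("cannot place clusters: mz_range too small for min_separation")
    charges = [z for z, _ in spec.charge_weights]
    weights = np.array([w for _, w in spec.charge_weights], dtype=float)
    weights /= weights.sum()
    for _ in range(500):
        # uniform positions subject to the separation: sample in the slack
        # interval, sort, then re-expand by the separation
        offsets = np.sort(rng.uniform(0.0, slack, size=n))
        monos = [float(lo + off + k * spec.min_separation) for k, off in enumerate(offsets)]
        clusters = []
        for mono in monos:
            # a fragment cannot outweigh its precursor: restrict the charge
            # draw to states whose neutral mass fits under M
            admissible = [z for z in charges
                          if (mono - M_H) * z <= spec.precursor_neutral_mass]
            if not admissible:
                admissible = [min(charges)]
            w = np.array([weights[charges.index(z)] for z in admissible])
            z = int(rng.choice(admissible, p=w / w.sum()))
            mass = (mono - M_H) * z
            n_peaks = 3 if mass >= spec.three_peak_mass else 2
            scale = float(np.exp(rng.uniform(math.log(300.0), math.log(3000.0))))
            clusters.append(PlantedCluster(
                mono_mz=mono, charge=z, n_peaks=n_peaks, intensity_scale=scale))
        if _layout_silent(clusters, spec.precursor_neutral_mass):
            return clusters
    raise ValueError("could not sample a clause-silent cluster layout")


def generate(spec: SyntheticSpec) -> tuple[Spectrum, list[PlantedCluster]]:
    """Build one synthetic spectrum and its ground truth.

    Deterministic given ``spec.seed``.  Envelope intensities follow the
    averagine mean envelope at each planted mass; decorations and noise
    are added per the spec; Gaussian m/z jitter is applied last (ground
    truth keeps the ideal positions).
    """
    rng = np.random.default_rng(spec.seed)
    truth = list(spec.clusters) if spec.clusters else _sample_clusters(spec, rng)
    positions: list[float] = []
    heights: list[float] = []
    base_peaks: list[float] = []
    for cluster in truth:
        ints = cluster.intensities()
        positions.extend(cluster.member_mzs)
        heights.extend(ints)
        base_peaks.append(max(ints))
    positions, heights = _merge_peaks(positions, heights)
    n_envelope_peaks = len(positions)

    M = spec.precursor_neutral_mass
    precursor_mz = (M + spec.precursor_charge * M_H) / spec.precursor_charge
    spectrum = Spectrum.from_arrays(positions, heights, precursor_mz,
                                    spec.precursor_charge,
                                    title=f"synthetic seed={spec.seed}")
    if spec.decorate:
        spectrum = complement_decorate(
            spectrum, truth, M,
            n_complements=spec.n_complements,
            satellites=spec.satellites,
            residue_partners=spec.residue_partners,
            collision_window=spec.collision_window,
        )

    mzs = list(spectrum.mz_array)
    intensities = list(spectrum.intensity_array)
    n_noise = int(round(spec.noise_fraction * n_envelope_peaks))
    median_base = float(np.median(base_peaks)) if base_peaks else 1.0
    lo = spec.mz_range[0]
    hi = max(mzs) if mzs else spec.mz_range[1]
    # noise must not manufacture truth-like evidence: besides the isotopic
    # chain screen, it may not land in a feature-clause window of an
    # arrangement-critical (interior, singly-claimed) planted peak
    harmful = _harmful_peaks(truth)
    critical = [(mz, occ) for mz, occ in _cluster_occupancies(truth) if mz in harmful]
    placed = 0
    attempts = 0
    while placed < n_noise and attempts < 10000:
        attempts += 1
        q = float(rng.uniform(lo, hi))
        if _extends_chain(q, mzs, spec.collision_window):
            continue
        if not _feature_silent(q, critical, M, set(), DEFAULT_CONSTANTS,
                               DEFAULT_FEATURE_PARAMS):
            continue
        mzs.append(q)
        intensities.append(median_base * float(
            np.exp(rng.uniform(math.log(0.01), math.log(0.30)))))
        placed += 1

    if spec.mz_jitter > 0:
        mzs = [m + float(rng.normal(0.0, spec.mz_jitter)) for m in mzs]
    spectrum = Spectrum.from_arrays(mzs, intensities, precursor_mz,
                                    spec.precursor_charge,
                                    title=f"synthetic seed={spec.seed}")
    return spectrum, truth


ARCHETYPES = ("interleaved", "shared-two", "shared-one", "mixed-charge")


def overlap_archetype(
    kind: Literal["interleaved", "shared-two", "shared-one", "mixed-charge"],
    mono_mz: float = 600.0,
    intensity: float = 1000.0,
    seed: int = 0,
    decorate: bool = True,
    precursor_neutral_mass: float = 1800.0,
) -> tuple[Spectrum, list[PlantedCluster]]:
    """A spectrum realizing one of the canonical overlap configurations.

    * ``interleaved`` — two singly charged envelopes threaded through each
      other with no shared peak;
    * ``shared-two`` — two singly charged 3-peak envelopes sharing two
      peaks;
    * ``shared-one`` — a 3-peak envelope whose last peak starts a second
      2-peak envelope of the same charge;
    * ``mixed-charge`` — a doubly charged 3-peak envelope sharing its
      second peak with a singly charged 3-peak envelope.
    """
    m = mono_mz
    if kind == "interleaved":
        # a strong intensity disparity keeps the two interleaved envelopes
        # distinguishable from a single doubly charged envelope, whose
        # shape two near-equal overlapping envelopes would mimic
        clusters = [
            PlantedCluster(m, 1, 3, intensity),
            PlantedCluster(m + ISOTOPE_GAP / 2, 1, 2, 2.5 * intensity),
        ]
    elif kind == "shared-two":
        clusters = [
            PlantedCluster(m, 1, 3, intensity),
            PlantedCluster(m + ISOTOPE_GAP, 1, 3, 0.8 * intensity),
        ]
    elif kind == "shared-one":
        clusters = [
            PlantedCluster(m, 1, 3, intensity),
            PlantedCluster(m + 2 * ISOTOPE_GAP, 1, 2, 0.8 * intensity),
        ]
    elif kind == "mixed-charge":
        clusters = [
            PlantedCluster(m, 2, 3, intensity),
            PlantedCluster(m + ISOTOPE_GAP / 2, 1, 3, 0.8 * intensity),
        ]
    else:
        raise ValueError(f"unknown archetype {kind!r}")
    spec = SyntheticSpec(
        seed=seed,
        clusters=tuple(clusters),
        noise_fraction=0.0,
        mz_jitter=0.0,
        decorate=decorate,
        precursor_neutral_mass=precursor_neutral_mass,
    )
    return generate(spec)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Cluster-level comparison of pipeline output against planted truth."""

    n_truth: int
    n_recovered: int
    n_selected: int
    n_false: int

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else 1.0

    @property
    def false_rate(self) -> float:
        return self.n_false / self.n_selected if self.n_selected else 0.0

    def __add__(self, other: "RecoveryMetrics") -> "RecoveryMetrics":
        return RecoveryMetrics(
            self.n_truth + other.n_truth,
            self.n_recovered + other.n_recovered,
            self.n_selected + other.n_selected,
            self.n_false + other.n_false,
        )


def planted_recovery(
    ions: Sequence[DeisotopedIon],
    truth: Sequence[PlantedCluster],
    mz_tol: float = 0.01,
) -> RecoveryMetrics:
    """Match multi-peak output ions against planted clusters.

    A planted cluster is recovered if some selected (>= 2-peak) ion has
    the same charge and a monoisotopic m/z within ``mz_tol``; a selected
    ion matching no planted cluster counts as false.  Pass-through
    singleton ions are ignored on both sides.
    """
    selected = [ion for ion in ions if len(ion.member_indices) >= 2]
    recovered = 0
    for cluster in truth:
        if any(ion.charge == cluster.charge
               and abs(ion.mono_mz - cluster.mono_mz) <= mz_tol
               for ion in selected):
            recovered += 1
    false = 0
    for ion in selected:
        if not any(ion.charge == cluster.charge
                   and abs(ion.mono_mz - cluster.mono_mz) <= mz_tol
                   for cluster in truth):
            false += 1
    return RecoveryMetrics(
        n_truth=len(truth),
        n_recovered=recovered,
        n_selected=len(selected),
        n_false=false,
    )
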