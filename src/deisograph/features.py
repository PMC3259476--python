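"""The five fragment-ion features and the weighted cluster score.

Four *non-intensity* features count peaks elsewhere in the spectrum that
support the hypothesis that a peak ``x`` belongs to a real CID fragment
ion:

* **F1** — sequence-ladder partners: peaks whose mass difference with x
  matches an amino-acid residue mass;
* **F2** — complementary fragments: peaks whose mass sum with x matches
  the precursor neutral mass (b/y-type complementarity);
* **F3** — neutral-loss satellites: water or ammonia loss differences;
* **F4** — supportive ion series: a-ions (b - CO) and z-ions (y - NH).

Each feature evaluates nine clauses built from the diff/sum variables,
which cover the charge combinations (1,1), (2,1), (3,1) and (3,2) of the
x/y pair; every printed equality ``expr = target + θ`` is read as the
symmetric window ``|expr - target| <= θ``.

The *intensity* feature **F5** counts cluster members whose observed
relative intensity falls near the theoretical envelope bracket predicted
from the cluster's mass; when the cluster shares peaks with an adjacent
cluster in the graph, the partner's predicted mean envelope is first
subtracted from the shared peaks.

The cluster score is the weighted sum ``Σ_f ω_f F_f`` accumulated over
all member peaks, with default weights ω = (0.8, 0.5, 0.1, 0.1, 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cluster_search import CandidateCluster
from .constants import DEFAULT_CONSTANTS, MassConstants
from .isotope_model import DEFAULT_MODELS, elemental_distribution
from .spectrum import Peak, Spectrum

__all__ = [
    "ScoreWeights",
    "FeatureParams",
    "diff_sum",
    "feature_F1",
    "feature_F2",
    "feature_F3",
    "feature_F4",
    "feature_F5",
    "score_cluster",
    "ClusterScorer",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Linear-combination coefficients of the five features."""

    w1: float = 0.8
    w2: float = 0.5
    w3: float = 0.1
    w4: float = 0.1
    w5: float = 0.1

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.w1, self.w2, self.w3, self.w4, self.w5)

    def scaled(self, factor: float) -> "ScoreWeights":
        return ScoreWeights(*(w * factor for w in self.as_tuple()))


@dataclass(frozen=True)
class FeatureParams:
    """Tolerances of the feature clauses.

    ``theta`` (Da) is the symmetric match window of the F1-F4 clauses;
    ``f5_threshold`` bounds the normalized envelope residual of F5.
    ``f2_offset_mode`` selects the per-position precursor-mass offset in
    F2: ``verbatim`` adds 2 Da per isotope position, ``isotopic`` adds the
    physically motivated 1.003 Da per position.
    """

    theta: float = 0.3
    f5_threshold: float = 0.3
    f2_offset_mode: Literal["verbatim", "isotopic"] = "verbatim"

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if not self.f5_threshold > 0:
            raise ValueError("f5_threshold must be positive")
        if self.f2_offset_mode not in ("verbatim", "isotopic"):
            raise ValueError(f"unknown f2_offset_mode {self.f2_offset_mode!r}")

    def f2_offset(self, i: int) -> float:
        return 2.0 * i if self.f2_offset_mode == "verbatim" else 1.003 * i


DEFAULT_FEATURE_PARAMS = FeatureParams()


def diff_sum(x: float, y: float, variant: int, mode: Literal["diff", "sum"],
             m_h: float = DEFAULT_CONSTANTS.M_H) -> float:
    """The eight diff/sum variables relating two peak m/z values.

    Variants 1-4 correspond to the charge pairings (z_x, z_y) = (z, z),
    (2, 1), (3, 1) and (3, 2).
    """
    if mode == "diff":
        if variant == 1:
            return x - y
        if variant == 2:
            return x - y + m_h / 2
        if variant == 3:
            return x - y + 2 * m_h / 3
        if variant == 4:
            return x - 2 * y + m_h / 3
    elif mode == "sum":
        if variant == 1:
            return x + y
        if variant == 2:
            return x + y + m_h / 2
        if variant == 3:
            return x + y + 2 * m_h / 3
        if variant == 4:
            return x + 2 * y + m_h / 3
    raise ValueError(f"invalid diff/sum variant {variant!r} or mode {mode!r}")


def _other_mzs(x: Peak, spectrum: Spectrum) -> np.ndarray:
    """m/z of every spectrum peak except x itself (by index)."""
    mzs = spectrum.mz_array
    return np.delete(mzs, x.index) if 0 <= x.index < len(mzs) else mzs


def _any_match(expr: np.ndarray, targets: np.ndarray, theta: float) -> np.ndarray:
    """Boolean per y: does expr land within theta of any target."""
    if expr.size == 0 or targets.size == 0:
        return np.zeros(expr.shape, dtype=bool)
    return (np.abs(expr[:, None] - targets[None, :]) <= theta).any(axis=1)


def _diff_feature(x_mz: float, ys: np.ndarray, base_targets: np.ndarray,
                  theta: float, m_h: float) -> int:
    """Shared nine-clause structure of F1, F3 and F4.

    Clause layout: |diff1| against targets, targets/2 and targets/3;
    |diff2| (both argument orders) against targets/2; |diff3| and |diff4|
    (both orders) against targets/3.
    """
    d1 = x_mz - ys
    d2_xy = d1 + m_h / 2
    d2_yx = -d1 + m_h / 2
    d3_xy = d1 + 2 * m_h / 3
    d3_yx = -d1 + 2 * m_h / 3
    d4_xy = x_mz - 2 * ys + m_h / 3
    d4_yx = ys - 2 * x_mz + m_h / 3
    t1 = base_targets
    t2 = base_targets / 2
    t3 = base_targets / 3
    hit = _any_match(np.abs(d1), t1, theta)
    hit |= _any_match(np.abs(d1), t2, theta)
    hit |= _any_match(np.abs(d1), t3, theta)
    hit |= _any_match(np.abs(d2_xy), t2, theta)
    hit |= _any_match(np.abs(d2_yx), t2, theta)
    hit |= _any_match(np.abs(d3_xy), t3, theta)
    hit |= _any_match(np.abs(d3_yx), t3, theta)
    hit |= _any_match(np.abs(d4_xy), t3, theta)
    hit |= _any_match(np.abs(d4_yx), t3, theta)
    return int(hit.sum())


def feature_F1(x: Peak, spectrum: Spectrum,
               consts: MassConstants = DEFAULT_CONSTANTS,
               params: FeatureParams = DEFAULT_FEATURE_PARAMS) -> int:
    """Count of peaks y whose difference with x matches a residue mass."""
    targets = np.array(sorted(set(consts.residue_masses.values())), dtype=float)
    return _diff_feature(x.mz, _other_mzs(x, spectrum), targets, params.theta, consts.M_H)


def feature_F2(x: Peak, isotope_position_i: int, spectrum: Spectrum, M: float,
               consts: MassConstants = DEFAULT_CONSTANTS,
               params: FeatureParams = DEFAULT_FEATURE_PARAMS) -> int:
    """Count of peaks y complementary to x against the precursor mass M.

    ``isotope_position_i`` is x's 0-based position within its candidate
    cluster; the precursor mass target is offset per position (by 2 Da per
    position in the verbatim mode).
    """
    ys = _other_mzs(x, spectrum)
    m_h = consts.M_H
    base = M + params.f2_offset(isotope_position_i)
    t1 = np.array([base + 2 * m_h])
    t2 = np.array([base / 2 + 2 * m_h])
    t3 = np.array([base / 3 + 2 * m_h])
    s1 = x.mz + ys
    s2 = s1 + m_h / 2        # sum2 is symmetric in its arguments
    s3 = s1 + 2 * m_h / 3    # so is sum3
    s4_xy = x.mz + 2 * ys + m_h / 3
    s4_yx = ys + 2 * x.mz + m_h / 3
    theta = params.theta
    hit = _any_match(s1, t1, theta)
    hit |= _any_match(s1, t2, theta)
    hit |= _any_match(s1, t3, theta)
    hit |= _any_match(s2, t2, theta)
    hit |= _any_match(s3, t3, theta)
    hit |= _any_match(s4_xy, t3, theta)
    hit |= _any_match(s4_yx, t3, theta)
    return int(hit.sum())


def feature_F3(x: Peak, spectrum: Spectrum,
               consts: MassConstants = DEFAULT_CONSTANTS,
               params: FeatureParams = DEFAULT_FEATURE_PARAMS) -> int:
    """Count of peaks y at a water- or ammonia-loss difference from x."""
    targets = np.array([consts.M_H2O, consts.M_NH3])
    return _diff_feature(x.mz, _other_mzs(x, spectrum), targets, params.theta, consts.M_H)


def feature_F4(x: Peak, spectrum: Spectrum,
               consts: MassConstants = DEFAULT_CONSTANTS,
               params: FeatureParams = DEFAULT_FEATURE_PARAMS) -> int:
    """Count of supportive-series peaks (a-ion CO and z-ion NH offsets)."""
    targets = np.array([consts.M_CO, consts.M_NH])
    return _diff_feature(x.mz, _other_mzs(x, spectrum), targets, params.theta, consts.M_H)


def _model_envelopes(mass: float, length: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t_min, t_mean, t_max) truncated to ``length`` and renormalized.

    Each composition model's distribution is renormalized over the
    retained positions before taking elementwise extremes, so a 2-peak
    cluster is compared against 2-position envelope shapes.
    """
    dists = []
    mean = None
    for model in DEFAULT_MODELS:
        d = elemental_distribution(model.formula_for_mass(mass), n_isotopes=length)
        dists.append(d)
        if model.name == "averagine":
            mean = d
    stacked = np.vstack(dists)
    return stacked.min(axis=0), mean, stacked.max(axis=0)


def feature_F5(cluster: CandidateCluster,
               overlap_partner: CandidateCluster | None = None,
               params: FeatureParams = DEFAULT_FEATURE_PARAMS,
               envelope: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
               partner_mean: np.ndarray | None = None) -> int:
    """Envelope-agreement count for one candidate cluster.

    Observed member intensities are normalized to unit sum (E).  For every
    member after the first (the anchor), the criterion

        min(|E_i - Tmin_i|, |E_i - Tmax_i|) / Tmean_i <= threshold

    must hold for the member to count.  If ``overlap_partner`` shares
    peaks with the cluster, the partner's unit-normalized mean envelope is
    subtracted from the shared members' E before the test.

    ``envelope``/``partner_mean`` allow precomputed theoretical vectors to
    be injected; they default to the extreme-composition predictions at
    each cluster's neutral-mass estimate.
    """
    length = len(cluster)
    if envelope is None:
        envelope = _model_envelopes(cluster.neutral_mass, length)
    t_min, t_mean, t_max = (np.asarray(v, dtype=float) for v in envelope)
    if len(t_mean) < length:
        raise ValueError("envelope shorter than cluster")
    t_min, t_mean, t_max = t_min[:length], t_mean[:length], t_max[:length]
    intensities = np.array([p.intensity for p in cluster.peaks], dtype=float)
    total = intensities.sum()
    if total <= 0:
        return 0
    e = intensities / total
    if overlap_partner is not None:
        shared = set(cluster.member_indices) & set(overlap_partner.member_indices)
        if shared:
            if partner_mean is None:
                partner_mean = _model_envelopes(
                    overlap_partner.neutral_mass, len(overlap_partner))[1]
            partner_mean = np.asarray(partner_mean, dtype=float)
            for idx in shared:
                i = cluster.member_indices.index(idx)
                j = overlap_partner.member_indices.index(idx)
                e[i] = e[i] - partner_mean[j]
    count = 0
    for i in range(1, length):  # members after the anchor peak
        residual = min(abs(e[i] - t_min[i]), abs(e[i] - t_max[i]))
        if t_mean[i] > 0 and residual / t_mean[i] <= params.f5_threshold:
            count += 1
    return count


def score_cluster(cluster: CandidateCluster,
                  relationship: CandidateCluster | None,
                  spectrum: Spectrum,
                  weights: ScoreWeights = ScoreWeights(),
                  consts: MassConstants = DEFAULT_CONSTANTS,
                  params: FeatureParams = DEFAULT_FEATURE_PARAMS) -> float:
    """Weighted feature score of one candidate cluster.

    ``relationship`` is the overlapping predecessor cluster when the
    cluster is scored as the tail of a red (shared-peak) arc, else None.
    The score is the sum over member peaks of ``Σ ω_f F_f``; F5
    contributes the per-member envelope-agreement indicators.
    """
    M = spectrum.precursor_neutral_mass
    total = 0.0
    for i, peak in enumerate(cluster.peaks):
        total += weights.w1 * feature_F1(peak, spectrum, consts, params)
        total += weights.w2 * feature_F2(peak, i, spectrum, M, consts, params)
        total += weights.w3 * feature_F3(peak, spectrum, consts, params)
        total += weights.w4 * feature_F4(peak, spectrum, consts, params)
    total += weights.w5 * feature_F5(cluster, relationship, params)
    return total


class ClusterScorer:
    """Cached scorer for all candidate clusters of one spectrum.

    F1, F3 and F4 depend only on the peak, and F2 on the (peak, position)
    pair, so their counts are memoized across the many clusters a peak may
    belong to.  Theoretical envelopes are memoized by (mass, length).
    """

    def __init__(self, spectrum: Spectrum,
                 weights: ScoreWeights = ScoreWeights(),
                 consts: MassConstants = DEFAULT_CONSTANTS,
                 params: FeatureParams = DEFAULT_FEATURE_PARAMS) -> None:
        self.spectrum = spectrum
        self.weights = weights
        self.consts = consts
        self.params = params
        self._per_peak: dict[int, float] = {}
        self._f2: dict[tuple[int, int], int] = {}
        self._envelopes: dict[tuple[float, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _peak_base(self, peak: Peak) -> float:
        if peak.index not in self._per_peak:
            self._per_peak[peak.index] = (
                self.weights.w1 * feature_F1(peak, self.spectrum, self.consts, self.params)
                + self.weights.w3 * feature_F3(peak, self.spectrum, self.consts, self.params)
                + self.weights.w4 * feature_F4(peak, self.spectrum, self.consts, self.params)
            )
        return self._per_peak[peak.index]

    def _f2_count(self, peak: Peak, i: int) -> int:
        key = (peak.index, i)
        if key not in self._f2:
            self._f2[key] = feature_F2(peak, i, self.spectrum,
                                       self.spectrum.precursor_neutral_mass,
                                       self.consts, self.params)
        return self._f2[key]

    def envelope(self, mass: float, length: int):
        key = (round(mass, 6), length)
        if key not in self._envelopes:
            self._envelopes[key] = _model_envelopes(mass, length)
        return self._envelopes[key]

    def score(self, cluster: CandidateCluster,
              relationship: CandidateCluster | None = None) -> float:
        total = 0.0
        for i, peak in enumerate(cluster.peaks):
            total += self._peak_base(peak)
            total += self.weights.w2 * self._f2_count(peak, i)
        env = self.envelope(cluster.neutral_mass, len(cluster))
        partner_mean = None
        if relationship is not None:
            partner_mean = self.envelope(relationship.neutral_mass, len(relationship))[1]
        total += self.weights.w5 * feature_F5(
            cluster, relationship, self.params, envelope=env, partner_mean=partner_mean)
        return total
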