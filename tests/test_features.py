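"""The diff/sum variables, features F1-F5 and the weighted score."""

import numpy as np
import pytest

from deisograph.cluster_search import CandidateCluster
from deisograph.constants import DEFAULT_CONSTANTS, M_H
from deisograph.features import (ClusterScorer, FeatureParams, ScoreWeights,
                                 _model_envelopes, diff_sum, feature_F1,
                                 feature_F2, feature_F3, feature_F4,
                                 feature_F5, score_cluster)
from deisograph.spectrum import Peak
from tests._oracles import (oracle_F1, oracle_F2, oracle_F3, oracle_F4,
                            oracle_F5)
from tests.conftest import make_spectrum


def test_diff_sum_printed_expressions():
    assert diff_sum(171.0788, 100.0, 1, "diff") == pytest.approx(71.0788)
    assert diff_sum(256.1875, 100.0, 1, "diff") == pytest.approx(156.1875)
    assert diff_sum(5.0, 5.0, 1, "diff") == 0.0
    assert diff_sum(100.0, 200.0, 2, "sum") == pytest.approx(300.0 + M_H / 2)
    assert diff_sum(100.0, 200.0, 2, "sum") == pytest.approx(300.5039125)
    assert diff_sum(10.0, 3.0, 4, "diff") == pytest.approx(10 - 6 + M_H / 3)
    assert diff_sum(10.0, 3.0, 4, "sum") == pytest.approx(10 + 6 + M_H / 3)


def test_diff_sum_invalid_variant():
    with pytest.raises(ValueError):
        diff_sum(1.0, 1.0, 5, "diff")
    with pytest.raises(ValueError):
        diff_sum(1.0, 1.0, 1, "weird")


def test_F1_alanine_arginine_partners():
    spectrum = make_spectrum([100.0, 171.0788, 256.1875])
    assert feature_F1(spectrum.peaks[0], spectrum) == 2


def test_F1_single_peak_spectrum():
    spectrum = make_spectrum([100.0])
    assert feature_F1(spectrum.peaks[0], spectrum) == 0


def test_F2_exact_complement_at_position_zero():
    M = 1800.0
    x = 600.0
    y = M + 2 * M_H - x
    spectrum = make_spectrum([x, y])
    assert feature_F2(spectrum.peaks[0], 0, spectrum, M) >= 1


def test_F3_water_loss_partner():
    spectrum = make_spectrum([500.0, 518.010565])
    assert feature_F3(spectrum.peaks[0], spectrum) >= 1


def test_F3_no_partner():
    spectrum = make_spectrum([500.0, 600.0])
    assert feature_F3(spectrum.peaks[0], spectrum) == 0


def test_F4_co_loss_partner():
    spectrum = make_spectrum([300.0 - 27.994915, 300.0])
    assert feature_F4(spectrum.peaks[1], spectrum) >= 1


@pytest.mark.parametrize("trial", range(30))
def test_features_match_bruteforce_oracles(trial):
    rng = np.random.default_rng(777 + trial)
    n = int(rng.integers(3, 50))
    mzs = np.sort(rng.uniform(80, 1500, size=n))
    spectrum = make_spectrum(mzs)
    M = spectrum.precursor_neutral_mass
    residues = list(DEFAULT_CONSTANTS.residue_masses.values())
    for idx in rng.choice(n, size=min(n, 4), replace=False):
        x = spectrum.peaks[int(idx)]
        ys = [p.mz for p in spectrum.peaks if p.index != x.index]
        assert feature_F1(x, spectrum) == oracle_F1(x.mz, ys, residues)
        assert feature_F3(x, spectrum) == oracle_F3(x.mz, ys)
        assert feature_F4(x, spectrum) == oracle_F4(x.mz, ys)
        for i in (0, 1, 2):
            assert feature_F2(x, i, spectrum, M) == oracle_F2(x.mz, i, ys, M)


def test_feature_monotone_in_added_support():
    base = make_spectrum([100.0, 400.0])
    more = make_spectrum([100.0, 171.0788, 400.0])
    assert feature_F1(more.peaks[0], more) >= feature_F1(base.peaks[0], base)


def _cluster(mzs, intensities, charge, start_index=0):
    peaks = tuple(Peak(mz=m, intensity=v, index=start_index + k)
                  for k, (m, v) in enumerate(zip(mzs, intensities)))
    return CandidateCluster(peaks=peaks, charge=charge)


def test_F5_mean_envelope_counts_all_tested_peaks():
    mass = 1200.0
    mono = mass / 2 + M_H
    t_min, t_mean, t_max = _model_envelopes(mass, 3)
    mzs = [mono, mono + 0.5015, mono + 1.003]
    cluster = _cluster(mzs, list(1000 * t_mean), 2)
    assert feature_F5(cluster) == 2


def test_F5_flat_pattern_fails_for_heavy_ion():
    mono = 2000.0 + M_H
    cluster = _cluster([mono, mono + 1.003, mono + 2.006], [1.0, 0.0, 0.0], 1)
    t_min, t_mean, t_max = _model_envelopes(2000.0, 3)
    want = oracle_F5([1.0, 0.0, 0.0], t_min, t_mean, t_max)
    assert feature_F5(cluster) == want
    assert feature_F5(cluster) == 0


@pytest.mark.parametrize("trial", range(20))
def test_F5_matches_literal_transcription(trial):
    rng = np.random.default_rng(31 + trial)
    charge = int(rng.integers(1, 4))
    length = int(rng.integers(2, 4))
    mono = float(rng.uniform(300, 1200))
    intensities = list(rng.uniform(1, 1000, size=length))
    cluster = _cluster([mono + k * 1.003 / charge for k in range(length)],
                       intensities, charge)
    env = _model_envelopes(cluster.neutral_mass, length)
    assert feature_F5(cluster, envelope=env) == oracle_F5(
        intensities, *[list(v) for v in env])


def test_F5_overlap_correction_subtracts_partner_mean():
    # two z=1 triples sharing two peaks with purely additive envelopes
    mono = 900.0
    _, t_mean_a, _ = _model_envelopes((mono - M_H), 3)
    _, t_mean_b, _ = _model_envelopes((mono + 1.003 - M_H), 3)
    a_int = 1000 * t_mean_a
    b_int = 1000 * t_mean_b
    merged = [a_int[0], a_int[1] + b_int[0], a_int[2] + b_int[1], b_int[2]]
    head = _cluster([mono, mono + 1.003, mono + 2.006],
                    merged[:3], 1, start_index=0)
    tail = _cluster([mono + 1.003, mono + 2.006, mono + 3.009],
                    merged[1:], 1, start_index=1)
    corrected = feature_F5(tail, overlap_partner=head)
    uncorrected = feature_F5(tail)
    assert corrected >= uncorrected


def test_score_zero_when_no_features():
    spectrum = make_spectrum([500.0, 500.5015])
    cluster = _cluster([500.0, 500.5015], [1.0, 0.0], 2)
    score = score_cluster(cluster, None, spectrum)
    assert score == pytest.approx(0.0)


def test_single_F1_peak_scores_w1():
    # one member has exactly one residue partner; suppress F5 by a
    # grossly non-isotopic intensity pattern at high mass
    mono = 2000.0
    spectrum = make_spectrum([mono, mono + 1.003, mono + 71.03711],
                             intensities=[1000.0, 0.0, 5.0],
                             precursor_mz=2500.0, precursor_charge=2)
    cluster = _cluster([mono, mono + 1.003], [1000.0, 0.0], 1)
    score = score_cluster(cluster, None, spectrum)
    n_f1 = (feature_F1(spectrum.peaks[0], spectrum)
            + feature_F1(spectrum.peaks[1], spectrum))
    assert n_f1 >= 1
    assert score == pytest.approx(0.8 * n_f1)


def test_score_linear_in_weights(rng):
    mzs = np.sort(rng.uniform(200, 1200, size=25))
    spectrum = make_spectrum(mzs)
    sub = [p for p in spectrum.peaks[:2]]
    cluster = CandidateCluster(peaks=tuple(sub), charge=1) if \
        abs(sub[1].mz - sub[0].mz - 1.003) < 0.01 else _cluster(
            [400.0, 401.003], [3.0, 1.0], 1)
    w = ScoreWeights()
    s1 = score_cluster(cluster, None, spectrum, weights=w)
    s2 = score_cluster(cluster, None, spectrum, weights=w.scaled(2.0))
    assert s2 == pytest.approx(2 * s1)


def test_scorer_matches_direct_composition(rng):
    mzs = np.sort(rng.uniform(200, 1200, size=30))
    spectrum = make_spectrum(mzs)
    scorer = ClusterScorer(spectrum)
    cluster = _cluster([mzs[0], mzs[0] + 1.003], [10.0, 4.0], 1)
    assert scorer.score(cluster) == pytest.approx(
        score_cluster(cluster, None, spectrum))


def test_same_peak_scores_differently_in_different_clusters():
    # the shared peak sits at position 1 of the first cluster and at
    # position 0 of the second; its complement fires only at position 1
    M = 1800.0
    mono = 500.0
    shared = mono + 1.003
    complement = M + 2 * 1 + 2 * M_H - shared  # supports position 1 only
    spectrum = make_spectrum([mono, shared, shared + 1.003, complement],
                             precursor_mz=M / 2 + M_H, precursor_charge=2)
    first = feature_F2(spectrum.peaks[1], 1, spectrum, M)
    second = feature_F2(spectrum.peaks[1], 0, spectrum, M)
    assert first >= 1
    assert first != second
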