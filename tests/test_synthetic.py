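"""The synthetic-spectrum generator and its ground-truth guarantees."""

import numpy as np
import pytest

from deisograph.constants import M_H
from deisograph.features import feature_F1, feature_F2, feature_F3
from deisograph.isotope_model import AVERAGINE_MODEL, elemental_distribution
from deisograph.synthetic import (ARCHETYPES, PlantedCluster, SyntheticSpec,
                                  complement_decorate, generate,
                                  overlap_archetype, planted_recovery)
from deisograph.spectrum import DeisotopedIon


def test_single_cluster_construction_exact():
    cluster = PlantedCluster(mono_mz=500.0, charge=2, n_peaks=3,
                             intensity_scale=1000.0)
    spec = SyntheticSpec(seed=0, clusters=(cluster,), noise_fraction=0.0,
                         mz_jitter=0.0, decorate=False)
    spectrum, truth = generate(spec)
    assert [round(p.mz, 4) for p in spectrum.peaks] == [500.0, 500.5015, 501.003]
    d = elemental_distribution(
        AVERAGINE_MODEL.formula_for_mass((500.0 - M_H) * 2), n_isotopes=3)
    want = 1000.0 * d / d.sum()
    np.testing.assert_allclose([p.intensity for p in spectrum.peaks], want)


def test_same_seed_identical_output():
    a, _ = generate(SyntheticSpec(seed=42))
    b, _ = generate(SyntheticSpec(seed=42))
    assert [p.mz for p in a.peaks] == [p.mz for p in b.peaks]
    assert [p.intensity for p in a.peaks] == [p.intensity for p in b.peaks]


def test_different_seeds_differ():
    a, _ = generate(SyntheticSpec(seed=1))
    b, _ = generate(SyntheticSpec(seed=2))
    assert [p.mz for p in a.peaks] != [p.mz for p in b.peaks]


def test_planted_gaps_exact_before_jitter():
    spectrum, truth = generate(SyntheticSpec(seed=7).clean())
    mzs = [p.mz for p in spectrum.peaks]
    for cluster in truth:
        for mz in cluster.member_mzs:
            assert any(abs(m - mz) < 1e-9 for m in mzs)


def test_noise_count_and_intensity_law():
    clean, truth = generate(SyntheticSpec(seed=3).clean())
    noisy, _ = generate(SyntheticSpec(seed=3, mz_jitter=0.0))
    n_envelope = len({round(mz, 4) for c in truth for mz in c.member_mzs})
    n_noise = len(noisy) - len(clean)
    assert n_noise == round(0.3 * n_envelope)
    base = np.median([max(c.intensities()) for c in truth])
    clean_mzs = {round(p.mz, 6) for p in clean.peaks}
    noise_ints = [p.intensity for p in noisy.peaks
                  if round(p.mz, 6) not in clean_mzs]
    assert all(0.01 * base * 0.999 <= v <= 0.30 * base * 1.001
               for v in noise_ints)


def test_decoration_fires_features_for_planted_members():
    spectrum, truth = generate(SyntheticSpec(seed=11).clean())
    M = spectrum.precursor_neutral_mass
    fired = 0
    total = 0
    for cluster in truth:
        for i, mz in enumerate(cluster.member_mzs):
            peak = min(spectrum.peaks, key=lambda p: abs(p.mz - mz))
            total += 1
            if feature_F2(peak, i, spectrum, M) > 0:
                fired += 1
    # clause windows of neighboring envelopes block some complement
    # positions, so coverage is partial; the majority must be supported
    assert fired / total >= 0.5
    assert fired >= len(truth)


def test_decorate_residue_partner_example():
    cluster = PlantedCluster(mono_mz=100.0, charge=1, n_peaks=2,
                             intensity_scale=100.0)
    spec = SyntheticSpec(seed=0, clusters=(cluster,), noise_fraction=0.0,
                         mz_jitter=0.0, decorate=False,
                         precursor_neutral_mass=900.0)
    spectrum, truth = generate(spec)
    decorated = complement_decorate(spectrum, truth, M=900.0,
                                    n_complements=0, satellites=False,
                                    residue_partners=True)
    mono = min(decorated.peaks, key=lambda p: abs(p.mz - 100.0))
    assert feature_F1(mono, decorated) >= 1
    # the added partner sits an exact residue mass above the mono peak
    added = [p.mz for p in decorated.peaks
             if all(abs(p.mz - q.mz) > 1e-9 for q in spectrum.peaks)]
    assert any(abs(q - 100.0 - 71.03711) < 1e-6 or q > 100.0 for q in added)


def test_decorate_satellites_fire_f3():
    cluster = PlantedCluster(mono_mz=500.0, charge=2, n_peaks=2,
                             intensity_scale=100.0)
    spec = SyntheticSpec(seed=0, clusters=(cluster,), noise_fraction=0.0,
                         mz_jitter=0.0, decorate=False)
    spectrum, truth = generate(spec)
    decorated = complement_decorate(spectrum, truth, satellites=True,
                                    n_complements=0, residue_partners=False)
    mono = min(decorated.peaks, key=lambda p: abs(p.mz - 500.0))
    assert feature_F3(mono, decorated) >= 1


@pytest.mark.parametrize("kind", ARCHETYPES)
def test_archetypes_construct_described_patterns(kind):
    spectrum, truth = overlap_archetype(kind, decorate=False)
    assert len(truth) == 2
    a, b = truth
    mzs_a, mzs_b = set(a.member_mzs), set(b.member_mzs)
    shared = {round(x, 4) for x in mzs_a} & {round(x, 4) for x in mzs_b}
    if kind == "interleaved":
        assert not shared
        assert min(mzs_b) > min(mzs_a) and max(mzs_b) < max(mzs_a)
    elif kind == "shared-two":
        assert len(shared) == 2
    elif kind == "shared-one":
        assert len(shared) == 1
    elif kind == "mixed-charge":
        assert len(shared) == 1
        assert a.charge != b.charge
    # shared peaks carry summed intensity
    n_unique = len({round(mz, 4) for c in truth for mz in c.member_mzs})
    assert len(spectrum) == n_unique


def test_recovery_metrics_accounting():
    truth = [PlantedCluster(500.0, 2, 3), PlantedCluster(800.0, 1, 2)]
    ions = [
        DeisotopedIon(500.001, 2, 10.0, (0, 1, 2)),     # recovered
        DeisotopedIon(650.0, 1, 5.0, (3, 4)),           # false
        DeisotopedIon(900.0, 1, 1.0, (7,)),             # singleton, ignored
    ]
    m = planted_recovery(ions, truth)
    assert m.n_truth == 2 and m.n_recovered == 1
    assert m.n_selected == 2 and m.n_false == 1
    assert m.recovery_rate == 0.5
    assert m.false_rate == 0.5


def test_charge_never_exceeds_precursor_capacity():
    for seed in range(5):
        _, truth = generate(SyntheticSpec(seed=seed))
        for c in truth:
            assert c.neutral_mass <= 1800.0 + 1e-6
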