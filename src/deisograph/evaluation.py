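"""Monoisotopic-peak evaluation: theoretical fragments and F-score curves.

Deconvolved ions are compared against the theoretical fragment ions of a
known peptide.  An experimental ion within the mass tolerance of some
theoretical peak is a true positive; the remaining experimental ions are
false positives and unmatched theoretical peaks are false negatives.  The
F-score is the harmonic mean of the resulting precision and recall,
traced over a grid of tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .constants import DEFAULT_CONSTANTS, MassConstants
from .spectrum import DeisotopedIon

__all__ = [
    "TheoreticalFragment",
    "TheoreticalSpectrum",
    "MatchCounts",
    "theoretical_fragments",
    "match_and_score",
    "f_score_curve",
]


@dataclass(frozen=True)
class TheoreticalFragment:
    ion_type: str    # e.g. "b2", "y3-H2O"
    charge: int
    mz: float


@dataclass(frozen=True)
class TheoreticalSpectrum:
    peptide: str
    fragments: tuple[TheoreticalFragment, ...]

    @property
    def mzs(self) -> list[float]:
        return [f.mz for f in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class MatchCounts:
    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


#: Primary fragment series and their m/z offsets at charge 1, relative to
#: the summed residue mass of the fragment.  b = residues + H; y adds the
#: C-terminal water; a/c derive from b by -CO/+NH3; x derives from y by
#: +CO-H2; the z series sits one NH below y (the supportive-ion offset).
def _series_offsets(c: MassConstants) -> dict[str, float]:
    return {
        "b": c.M_H,
        "a": c.M_H - c.M_CO,
        "c": c.M_H + c.M_NH3,
        "y": c.M_H2O + c.M_H,
        "x": c.M_H2O + c.M_H + c.M_CO - 2 * c.M_H,
        "z": c.M_H2O + c.M_H - c.M_NH,
    }


def theoretical_fragments(
    peptide: str,
    charges: Iterable[int] = (1,),
    consts: MassConstants = DEFAULT_CONSTANTS,
    ion_types: Sequence[str] = ("a", "b", "c", "x", "y", "z"),
    neutral_losses: bool = True,
) -> TheoreticalSpectrum:
    """All N- and C-terminal series fragments of a peptide.

    For a peptide of n residues each series has n-1 ions per charge.
    ``neutral_losses`` adds water- and ammonia-loss variants of the b and
    y series.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    masses = []
    for residue in peptide:
        if residue not in consts.residue_masses:
            raise ValueError(f"unknown residue {residue!r}")
        masses.append(consts.residue_masses[residue])
    n = len(masses)
    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)
    offsets = _series_offsets(consts)
    fragments: list[TheoreticalFragment] = []

    def add(label: str, mz1: float, charge: int) -> None:
        mz = (mz1 + (charge - 1) * consts.M_H) / charge
        fragments.append(TheoreticalFragment(ion_type=label, charge=charge, mz=mz))

    for k in range(1, n):
        nterm = prefix[k]
        cterm = prefix[n] - prefix[k]
        for z in charges:
            for series in ion_types:
                if series not in offsets:
                    raise ValueError(f"unknown ion series {series!r}")
                frag = nterm if series in ("a", "b", "c") else cterm
                idx = k if series in ("a", "b", "c") else n - k
                add(f"{series}{idx}", frag + offsets[series], z)
            if neutral_losses:
                for series, frag, idx in (("b", nterm, k), ("y", cterm, n - k)):
                    if series in ion_types:
                        base = frag + offsets[series]
                        add(f"{series}{idx}-H2O", base - consts.M_H2O, z)
                        add(f"{series}{idx}-NH3", base - consts.M_NH3, z)
    return TheoreticalSpectrum(peptide=peptide, fragments=tuple(fragments))


def match_and_score(
    experimental: Sequence[DeisotopedIon] | Sequence[float],
    theoretical: TheoreticalSpectrum | Sequence[float],
    tolerance: float,
    single_charge_space: bool = True,
) -> MatchCounts:
    """Greedy one-to-one matching of experimental vs theoretical peaks.

    By default both sides are compared as charge-1-equivalent m/z values
    (deisotoped data has known charges, theoretical fragments are
    generated at 1+), so ions of any native charge can match.  Candidate
    pairs are matched greedily by ascending mass difference; each peak
    matches at most once.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if isinstance(theoretical, TheoreticalSpectrum):
        theo = theoretical.mzs
    else:
        theo = [float(t) for t in theoretical]
    exp: list[float] = []
    for ion in experimental:
        if isinstance(ion, DeisotopedIon):
            exp.append(ion.single_charge_mz() if single_charge_space else ion.mono_mz)
        else:
            exp.append(float(ion))
    pairs = sorted(
        (abs(e - t), ei, ti)
        for ei, e in enumerate(exp)
        for ti, t in enumerate(theo)
        if abs(e - t) <= tolerance
    )
    used_e: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, ei, ti in pairs:
        if ei in used_e or ti in used_t:
            continue
        used_e.add(ei)
        used_t.add(ti)
        tp += 1
    return MatchCounts(TP=tp, FP=len(exp) - tp, FN=len(theo) - tp)


def f_score_curve(
    experimental: Sequence[DeisotopedIon] | Sequence[float],
    theoretical: TheoreticalSpectrum | Sequence[float],
    tolerances: Sequence[float],
    single_charge_space: bool = True,
) -> list[tuple[float, MatchCounts]]:
    """Match counts over a grid of mass tolerances (e.g. 0 to 1 Da)."""
    if len(tolerances) == 0:
        raise ValueError("tolerance grid must be nonempty")
    return [
        (tol, match_and_score(experimental, theoretical, tol, single_charge_space))
        for tol in tolerances
    ]
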