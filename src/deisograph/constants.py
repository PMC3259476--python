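"""Mass constants shared across the package.

All masses are monoisotopic and given in Dalton.  High-resolution
instruments resolve the monoisotopic species, so average masses are never
used anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: Monoisotopic mass of a hydrogen atom (Da).  Used both for charge
#: conversions (m/z <-> neutral mass) and in the diff/sum variables of the
#: feature clauses.
M_H = 1.007825

#: Neutral-loss / supportive-ion mass offsets (Da).
M_H2O = 18.010565
M_NH3 = 17.026549
M_CO = 27.994915
M_NH = 15.010899

#: Monoisotopic residue masses of the twenty standard amino acids.
#: Isoleucine and leucine are isobaric but kept as separate entries so the
#: table has exactly twenty rows; lysine and glutamine differ by 0.036 Da
#: and remain distinct.
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
})

#: Average spacing between adjacent isotopic peaks of a singly charged ion
#: (Da).  For a charge-z ion the observed m/z spacing is ISOTOPE_GAP / z.
ISOTOPE_GAP = 1.003


@dataclass(frozen=True)
class MassConstants:
    """Bundle of the mass constants used by the feature clauses.

    Exposed as a dataclass so alternative constant sets (e.g. proton mass
    instead of hydrogen-atom mass) can be injected in one place.
    """

    M_H: float = M_H
    M_H2O: float = M_H2O
    M_NH3: float = M_NH3
    M_CO: float = M_CO
    M_NH: float = M_NH
    residue_masses: Mapping[str, float] = field(default_factory=lambda: RESIDUE_MASSES)

    def __post_init__(self) -> None:
        if len(self.residue_masses) != 20:
            raise ValueError(
                f"residue table must have exactly 20 entries, got {len(self.residue_masses)}"
            )
        for value in (self.M_H, self.M_H2O, self.M_NH3, self.M_CO, self.M_NH):
            if not value > 0:
                raise ValueError("mass constants must be positive")


DEFAULT_CONSTANTS = MassConstants()
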