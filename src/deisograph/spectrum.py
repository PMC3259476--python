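"""Core in-memory model of a centroided tandem mass spectrum.

A :class:`Spectrum` is an immutable, m/z-sorted list of :class:`Peak`
records plus precursor information.  The precursor neutral mass ``M`` is
derived from the precursor m/z and charge with the hydrogen-atom mass
convention ``M = z * mz - z * M_H`` and feeds the complementarity feature
of the scoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import M_H


@dataclass(frozen=True)
class Peak:
    """A single centroided peak.

    ``index`` is the ordinal position in the spectrum's m/z-sorted peak
    list and is the identity used for overlap tests between clusters.
    """

    mz: float
    intensity: float
    index: int

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


def neutral_mass(precursor_mz: float, charge: int, m_h: float = M_H) -> float:
    """Neutral (uncharged) mass from a precursor m/z and charge."""
    return charge * precursor_mz - charge * m_h


@dataclass(frozen=True)
class Spectrum:
    """An m/z-sorted centroided MS/MS spectrum with precursor annotation."""

    peaks: tuple[Peak, ...]
    precursor_mz: float
    precursor_charge: int
    title: str = ""

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.precursor_charge}")
        mzs = [p.mz for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must be sorted ascending by m/z")
        for i, p in enumerate(self.peaks):
            if p.index != i:
                raise ValueError("peak indices must equal their ordinal positions")

    @property
    def precursor_neutral_mass(self) -> float:
        """The paper-convention neutral precursor mass M."""
        return neutral_mass(self.precursor_mz, self.precursor_charge)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)

    def with_charge(self, charge: int) -> "Spectrum":
        return replace(self, precursor_charge=charge)

    @classmethod
    def from_arrays(
        cls,
        mzs: Sequence[float] | np.ndarray,
        intensities: Sequence[float] | np.ndarray,
        precursor_mz: float,
        precursor_charge: int,
        title: str = "",
    ) -> "Spectrum":
        """Build a spectrum from parallel m/z / intensity sequences.

        Peaks are sorted by m/z; duplicate m/z values are preserved as
        distinct peaks.
        """
        pairs = sorted(zip(map(float, mzs), map(float, intensities)))
        peaks = tuple(Peak(mz=m, intensity=it, index=i) for i, (m, it) in enumerate(pairs))
        return cls(peaks=peaks, precursor_mz=precursor_mz,
                   precursor_charge=precursor_charge, title=title)


@dataclass(frozen=True)
class DeisotopedIon:
    """Output record of the pipeline: one deconvolved fragment ion.

    ``mono_mz`` is the m/z of the monoisotopic peak at the ion's native
    charge; ``member_indices`` are the spectrum peak indices of the
    envelope (a single index for pass-through singleton peaks).
    """

    mono_mz: float
    charge: int
    intensity: float
    member_indices: tuple[int, ...]
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("ion charge must be >= 1")
        if not self.member_indices:
            raise ValueError("ion must reference at least one peak")
        if list(self.member_indices) != sorted(self.member_indices):
            raise ValueError("member indices must be sorted")
        if self.intensity < 0:
            raise ValueError("ion intensity must be non-negative")

    def single_charge_mz(self, m_h: float = M_H) -> float:
        """Charge-1-equivalent m/z: (mono_mz - M_H) * z + M_H."""
        return (self.mono_mz - m_h) * self.charge + m_h


def sorted_ions(ions: Iterable[DeisotopedIon]) -> list[DeisotopedIon]:
    return sorted(ions, key=lambda ion: (ion.mono_mz, ion.charge))
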