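"""Theoretical isotopic envelopes from extreme composition models.

A fragment ion's elemental composition is unknown in a tandem mass
spectrum, so its theoretical isotope pattern cannot be predicted exactly.
Instead, three extreme composition models bracket the pattern of any
peptide-like ion of a given mass:

* an all-phenylalanine polymer (C9H9NO) — carbon-rich, smallest
  monoisotopic fraction;
* the averagine average residue (the C4.949 H7.833 O1.473 N1.361 S0.038
  variant) — the mean case;
* an all-aspartate polymer (C4H5NO3) — oxygen-rich, largest monoisotopic
  fraction.

For a target mass the unit formula is scaled, C/N/O/S counts are rounded
and hydrogen absorbs the mass residual (the standard averagine
discretization).  Distributions are aggregated at nominal-isotope
resolution (+0/+1/+2 Da), which is sufficient because candidate clusters
never exceed three peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

#: Natural isotopic abundance by nominal mass shift (+0, +1, +2) for the
#: elements occurring in peptides (CODATA/IUPAC values).
ISOTOPE_ABUNDANCES: Mapping[str, tuple[float, ...]] = MappingProxyType({
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425),
})

#: Monoisotopic atomic masses (Da) used to scale unit formulas.
ATOMIC_MASSES: Mapping[str, float] = MappingProxyType({
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
})


@dataclass(frozen=True)
class CompositionModel:
    """A repeating-unit elemental composition (counts may be fractional)."""

    name: str
    unit_formula: Mapping[str, float]

    def __post_init__(self) -> None:
        for element, count in self.unit_formula.items():
            if element not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {element!r}")
            if count < 0:
                raise ValueError("element counts must be non-negative")

    @property
    def unit_mass(self) -> float:
        return sum(ATOMIC_MASSES[el] * n for el, n in self.unit_formula.items())

    def formula_for_mass(self, mass: float) -> dict[str, int]:
        """Integer formula approximating ``mass``.

        C, N, O and S are scaled and rounded; hydrogen is set last so that
        the formula's monoisotopic mass tracks the target as closely as an
        integer hydrogen count allows.
        """
        if not mass > 0:
            raise ValueError(f"mass must be positive, got {mass}")
        scale = mass / self.unit_mass
        formula: dict[str, int] = {}
        heavy_mass = 0.0
        for element, count in self.unit_formula.items():
            if element == "H":
                continue
            n = int(round(scale * count))
            if n > 0:
                formula[element] = n
                heavy_mass += n * ATOMIC_MASSES[element]
        n_h = max(int(round((mass - heavy_mass) / ATOMIC_MASSES["H"])), 0)
        if n_h > 0:
            formula["H"] = n_h
        return formula


PHENYLALANINE_MODEL = CompositionModel("all-phenylalanine", {"C": 9, "H": 9, "N": 1, "O": 1})
AVERAGINE_MODEL = CompositionModel(
    "averagine", {"C": 4.949, "H": 7.833, "O": 1.473, "N": 1.361, "S": 0.038}
)
ASPARTATE_MODEL = CompositionModel("all-aspartate", {"C": 4, "H": 5, "N": 1, "O": 3})

#: The three extreme-composition models, with averagine defining the mean.
DEFAULT_MODELS: tuple[CompositionModel, ...] = (
    PHENYLALANINE_MODEL,
    AVERAGINE_MODEL,
    ASPARTATE_MODEL,
)


@dataclass(frozen=True)
class EnvelopeBounds:
    """Per-isotope-index min/mean/max theoretical relative intensities.

    Vectors are indexed by isotope position (monoisotopic first) and each
    sums to one over the retained positions.
    """

    t_min: tuple[float, ...]
    t_mean: tuple[float, ...]
    t_max: tuple[float, ...]

    def __post_init__(self) -> None:
        for lo, mid, hi in zip(self.t_min, self.t_mean, self.t_max):
            if not (lo <= mid + 1e-12 and mid <= hi + 1e-12):
                raise ValueError("bounds must satisfy t_min <= t_mean <= t_max elementwise")

    def __len__(self) -> int:
        return len(self.t_mean)


def _power_truncated(dist: Sequence[float], n: int, length: int) -> np.ndarray:
    """``dist`` convolved with itself ``n`` times, truncated to ``length``.

    Exponentiation by squaring keeps the cost logarithmic in the atom
    count; truncation after every convolution is exact for the retained
    positions because discarded entries only feed higher isotope indices.
    """
    result = np.zeros(length)
    result[0] = 1.0
    base = np.asarray(dist, dtype=float)[:length]
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:length]
        base = np.convolve(base, base)[:length]
        n >>= 1
    return result


def elemental_distribution(
    formula: Mapping[str, int],
    n_isotopes: int = 3,
    abundances: Mapping[str, Sequence[float]] = ISOTOPE_ABUNDANCES,
) -> np.ndarray:
    """Aggregated isotope distribution of an integer elemental formula.

    Convolves the per-element isotope patterns at nominal-mass resolution,
    truncates to ``n_isotopes`` positions and renormalizes to sum one.
    """
    if n_isotopes < 1:
        raise ValueError("n_isotopes must be >= 1")
    dist = np.zeros(n_isotopes)
    dist[0] = 1.0
    for element, count in formula.items():
        if element not in abundances:
            raise ValueError(f"unknown element {element!r}")
        if count < 0 or count != int(count):
            raise ValueError(f"element counts must be non-negative integers, got {element}={count}")
        if count:
            dist = np.convolve(dist, _power_truncated(abundances[element], int(count), n_isotopes))
            dist = dist[:n_isotopes]
    total = dist.sum()
    if total <= 0:
        raise ValueError("degenerate isotope distribution")
    return dist / total


def envelope_bounds(
    mass: float,
    n_isotopes: int = 3,
    models: Sequence[CompositionModel] = DEFAULT_MODELS,
    mean_model: CompositionModel = AVERAGINE_MODEL,
    abundances: Mapping[str, Sequence[float]] = ISOTOPE_ABUNDANCES,
) -> EnvelopeBounds:
    """Min/mean/max theoretical envelope for an ion of the given mass.

    The mean is the averagine-model distribution; min and max are the
    elementwise extremes over all composition models (the conservative
    bracket of the unknown true composition).
    """
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    dists = []
    mean = None
    for model in models:
        dist = elemental_distribution(model.formula_for_mass(mass), n_isotopes, abundances)
        dists.append(dist)
        if model is mean_model:
            mean = dist
    if mean is None:
        mean = elemental_distribution(mean_model.formula_for_mass(mass), n_isotopes, abundances)
    stacked = np.vstack(dists + [mean])
    return EnvelopeBounds(
        t_min=tuple(stacked.min(axis=0)),
        t_mean=tuple(mean),
        t_max=tuple(stacked.max(axis=0)),
    )
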