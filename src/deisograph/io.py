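"""Reading and writing peak-list files (MGF and MS2).

Parsing is delegated to :mod:`pyteomics`; this module adapts the parsed
records to the package's :class:`~deisograph.spectrum.Spectrum` model and
enforces the conventions used downstream:

* the precursor neutral mass is ``z * mz - z * M_H`` (hydrogen-atom mass);
* MGF blocks without a CHARGE line default to 1+ (with a logged warning);
* MS2 scans carrying several Z lines are expanded to one spectrum per
  charge hypothesis, because the scoring stage assumes a single neutral
  precursor mass.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Literal, Sequence

import numpy as np
from pyteomics import mgf as _mgf
from pyteomics import ms2 as _ms2
from pyteomics.auxiliary import PyteomicsError

from .constants import M_H
from .spectrum import DeisotopedIon, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["ParseError", "read_mgf", "read_ms2", "read_spectra", "write_deconvolved_mgf"]


class ParseError(ValueError):
    """Raised when a peak-list file violates its format."""


def _block_title(params: dict, position: int) -> str:
    return str(params.get("title", f"block {position}"))


def read_mgf(path: str | os.PathLike) -> list[Spectrum]:
    """Read an MGF file into a list of spectra.

    Each BEGIN IONS / END IONS block yields one spectrum.  Peaks are
    re-sorted ascending by m/z if necessary.  A block without PEPMASS is a
    parse error; a block without CHARGE defaults to charge 1 with a
    warning.
    """
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
            for position, entry in enumerate(reader):
                params = entry.get("params", {})
                title = _block_title(params, position)
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    raise ParseError(f"{path}: missing PEPMASS in '{title}'")
                precursor_mz = float(pepmass[0])
                charges = params.get("charge")
                if charges:
                    charge = int(charges[0])
                else:
                    logger.warning("%s: block '%s' has no CHARGE line; assuming 1+", path, title)
                    charge = 1
                spectra.append(Spectrum.from_arrays(
                    entry["m/z array"], entry["intensity array"],
                    precursor_mz=precursor_mz, precursor_charge=charge, title=title,
                ))
    except PyteomicsError as exc:
        raise ParseError(f"{path}: malformed MGF ({exc})") from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: malformed MGF ({exc})") from exc
    return spectra


def read_ms2(path: str | os.PathLike) -> list[Spectrum]:
    """Read an MS2 file into a list of spectra.

    The Z line carries the charge and the singly-protonated mass
    ``M + M_H``; the precursor m/z at charge z is recovered as
    ``(M + z * M_H) / z``.  Scans with several Z lines are expanded to one
    spectrum per charge hypothesis sharing the peak list.
    """
    spectra: list[Spectrum] = []
    try:
        with _ms2.read(str(path), use_index=False, convert_arrays=1) as reader:
            for position, entry in enumerate(reader):
                params = entry.get("params", {})
                scan = params.get("scan")
                if scan is None:
                    raise ParseError(f"{path}: scan without S line (entry {position})")
                title = f"scan {scan[0]}"
                charges = params.get("charge") or []
                masses = params.get("neutral mass") or []
                if not charges:
                    raise ParseError(f"{path}: {title} has no Z line")
                for charge, mh_mass in zip(charges, masses):
                    z = int(charge)
                    neutral = float(mh_mass) - M_H  # Z line stores M + H
                    precursor_mz = (neutral + z * M_H) / z
                    spectra.append(Spectrum.from_arrays(
                        entry["m/z array"], entry["intensity array"],
                        precursor_mz=precursor_mz, precursor_charge=z,
                        title=f"{title} z={z}",
                    ))
    except PyteomicsError as exc:
        raise ParseError(f"{path}: malformed MS2 ({exc})") from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: malformed MS2 ({exc})") from exc
    return spectra


def read_spectra(path: str | os.PathLike,
                 fmt: Literal["mgf", "ms2", "auto"] = "auto") -> list[Spectrum]:
    """Dispatch on file format; ``auto`` decides from the extension."""
    if fmt == "auto":
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "ms2" if ext == ".ms2" else "mgf"
    if fmt == "mgf":
        return read_mgf(path)
    if fmt == "ms2":
        return read_ms2(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_deconvolved_mgf(
    spectra_with_ions: Iterable[tuple[Spectrum, Sequence[DeisotopedIon]]],
    path: str | os.PathLike,
    charge_mode: Literal["native", "single"] = "native",
) -> None:
    """Write deconvolved fragment ions back to MGF, one block per spectrum.

    Each ion becomes a single peak line.  In ``native`` mode the peak is
    the monoisotopic m/z at the ion's own charge; in ``single`` mode it is
    the charge-1 equivalent ``(mono_mz - M_H) * z + M_H``, which is the
    representation most search engines expect from deisotoped data.
    """
    entries = []
    for spectrum, ions in spectra_with_ions:
        if charge_mode == "single":
            mzs = [ion.single_charge_mz() for ion in ions]
        elif charge_mode == "native":
            mzs = [ion.mono_mz for ion in ions]
        else:
            raise ValueError(f"unknown charge mode {charge_mode!r}")
        order = np.argsort(mzs) if mzs else []
        entry = {
            "m/z array": np.array([mzs[i] for i in order], dtype=float),
            "intensity array": np.array([ions[i].intensity for i in order], dtype=float),
            "params": {
                "title": spectrum.title,
                "pepmass": (spectrum.precursor_mz,),
                "charge": f"{spectrum.precursor_charge}+",
            },
        }
        if charge_mode == "native":
            entry["charge array"] = np.array([ions[i].charge for i in order], dtype=int)
        entries.append(entry)
    _mgf.write(entries, str(path), file_mode="w")
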