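import sys
from pathlib import Path

import numpy as np
import pytest

from deisograph.spectrum import Spectrum

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers


def make_spectrum(mzs, intensities=None, precursor_mz=901.007825,
                  precursor_charge=2, title="test"):
    """Spectrum with M = 1800 Da by default."""
    if intensities is None:
        intensities = [100.0] * len(mzs)
    return Spectrum.from_arrays(mzs, intensities, precursor_mz,
                                precursor_charge, title=title)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spectrum_factory():
    return make_spectrum
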