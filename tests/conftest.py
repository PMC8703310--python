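import numpy as np
import pytest

from phosfit import (
    build_basis,
    default_tissue_axis,
    load_registry,
    make_axis,
)

REPORT_ENTRIES = ("ATP", "GPC", "PCr", "Pi")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def axis_1k():
    """Phantom-style axis: 2048 points over 1000 Hz at 49.9 MHz (±10 ppm)."""
    return make_axis(2048, 1000.0, 49.9)


@pytest.fixture(scope="session")
def axis_2k():
    """Tissue-style axis: 2048 points over 2000 Hz (±20 ppm)."""
    return default_tissue_axis()


@pytest.fixture(scope="session")
def fine_axis():
    """High-resolution axis for multiplet line counting."""
    return make_axis(16384, 2000.0, 49.9)


@pytest.fixture(scope="session")
def six_signal_basis(registry, axis_2k):
    """Basis restricted to the six-signal reporting subset."""
    return build_basis(registry, axis_2k, include=list(REPORT_ENTRIES),
                       fwhm_hz=1.0)


@pytest.fixture(scope="session")
def full_basis(registry, axis_2k):
    return build_basis(registry, axis_2k, fwhm_hz=1.0)


def count_maxima(freq, height_frac=0.15, prominence_frac=0.05):
    from scipy.signal import find_peaks

    mag = np.abs(freq)
    peaks, _ = find_peaks(mag, height=height_frac * mag.max(),
                          prominence=prominence_frac * mag.max())
    return len(peaks)
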