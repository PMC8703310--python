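"""Henderson–Hasselbalch pH from the Pi–PCr chemical-shift difference.

pH = pKa + log10((δ − δ_acid)/(δ_base − δ)) with the standard ³¹P Pi
calibration pKa = 6.75, δ_acid = 3.27 ppm, δ_base = 5.63 ppm; δ is the shift
of Pi relative to a pH-independent reference peak (PCr at 0 ppm).  The log
is base 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import PeakNotFoundError, ValidationError
from .simulation import Spectrum

__all__ = ["PhCalibration", "ph_from_shift", "shift_from_ph", "ph_from_spectrum"]

#: ppm positions (relative to the reference peak) where the two probe/reference
#: peaks are searched; half-widths of the search windows in ppm
_REFERENCE_SHIFTS = {"PCr": 0.0}
_SEARCH_HALFWIDTH = 0.75


@dataclass(frozen=True)
class PhCalibration:
    pka: float = 6.75
    delta_acid: float = 3.27   # ppm, fully protonated limit
    delta_base: float = 5.63   # ppm, fully deprotonated limit

    def __post_init__(self):
        if not (math.isfinite(self.pka) and self.delta_acid < self.delta_base):
            raise ValidationError("calibration requires finite pKa and delta_acid < delta_base")


DEFAULT_CALIBRATION = PhCalibration()


def ph_from_shift(delta: float, calibration: PhCalibration = DEFAULT_CALIBRATION) -> float:
    """pH from the Pi shift ``delta`` (ppm relative to the reference peak)."""
    a, b = calibration.delta_acid, calibration.delta_base
    if not (a < delta < b):
        raise ValidationError(
            f"shift {delta} ppm outside the open calibration interval "
            f"({a}, {b}) ppm; check the spectrum referencing")
    return calibration.pka + math.log10((delta - a) / (b - delta))


def shift_from_ph(ph: float, calibration: PhCalibration = DEFAULT_CALIBRATION) -> float:
    """Pi shift (ppm) at a given pH; saturates asymptotically at the limits."""
    if not math.isfinite(ph):
        raise ValidationError("ph must be finite")
    r = 10.0 ** (ph - calibration.pka)
    return (calibration.delta_acid + calibration.delta_base * r) / (1.0 + r)


def _peak_finder(spectrum: Spectrum, noise_window=(12.0, 18.0)):
    """Build a matched-filter peak locator for one spectrum.

    Detection correlates the pedestal-subtracted magnitude spectrum with a
    Lorentzian template whose width is taken from the tallest peak; the
    detection score is referenced to a signal-free noise region.  Candidate
    peaks are local maxima of the correlation (edge bins never qualify, so a
    neighbouring giant's tail cannot win the window).  Sub-grid positions
    come from a local least-squares fit of a complex Lorentzian around the
    detected bin, constrained to the search window.
    """
    mag = np.abs(spectrum.freq)
    mag = mag - float(np.median(mag))
    ppm = spectrum.axis.ppm

    # template width (bins) from the tallest peak's half-height span
    k = int(np.argmax(mag))
    half = mag[k] / 2.0
    left = k
    while left > 0 and mag[left] > half:
        left -= 1
    right = k
    while right < len(mag) - 1 and mag[right] > half:
        right += 1
    w_bins = max(right - left, 2)

    x = np.arange(-3 * w_bins, 3 * w_bins + 1)
    kern = 1.0 / (1.0 + (2.0 * x / w_bins) ** 2)
    corr = np.convolve(mag, kern / kern.sum(), mode="same")

    sel = (ppm >= noise_window[0]) & (ppm <= noise_window[1])
    if np.count_nonzero(sel) < 32:
        sel = np.zeros(len(ppm), dtype=bool)
        sel[: max(32, len(ppm) // 16)] = True  # highest-ppm edge
    noise_med = float(np.median(corr[sel]))
    noise_sd = float(np.std(corr[sel] - noise_med))

    def locate(lo: float, hi: float, threshold: float, name: str) -> float:
        window = (ppm > lo) & (ppm < hi)
        if not np.any(window):
            raise PeakNotFoundError(
                f"search window for '{name}' lies outside the axis")
        idx = np.nonzero(window)[0]
        # highest local maximum of the matched-filter response in the window
        interior = idx[(idx > 0) & (idx < len(corr) - 1)]
        is_max = (corr[interior] >= corr[interior - 1]) & \
                 (corr[interior] >= corr[interior + 1])
        candidates = interior[is_max]
        if candidates.size == 0:
            raise PeakNotFoundError(
                f"no local maximum for '{name}' inside the search window")
        j = int(candidates[np.argmax(corr[candidates])])
        score = (corr[j] - noise_med) / max(noise_sd, 1e-300)
        if noise_sd > 0 and score < threshold:
            raise PeakNotFoundError(
                f"peak '{name}' not detected above the prominence threshold")
        return _fit_lorentzian_position(spectrum.freq, ppm, j, w_bins, lo, hi)

    return locate


def _fit_lorentzian_position(freq: np.ndarray, ppm: np.ndarray, j: int,
                             w_bins: int, lo: float, hi: float) -> float:
    """Least-squares complex-Lorentzian fit around bin ``j``.

    Model: h·e^{iφ}·(γ/(γ + i(f−f0))) + complex offset, with γ the
    half-width; fitting the complex data exploits the phase information a
    magnitude fit discards.  The centre is constrained to (lo, hi); returns
    the fitted position in ppm.
    """
    halfwin = max(int(round(2.5 * w_bins)), 6)
    sel = np.zeros(len(ppm), dtype=bool)
    sel[max(j - halfwin, 0): min(j + halfwin + 1, len(ppm))] = True
    sel &= (ppm > lo) & (ppm < hi)
    y = np.concatenate([np.real(freq[sel]), np.imag(freq[sel])])
    f = ppm[sel]
    step = float(np.median(np.abs(np.diff(ppm))))
    gamma0 = max(0.5 * w_bins * step, 0.5 * step)

    def model(theta):
        h, phi, f0, gamma, cr, ci = theta
        line = h * np.exp(1j * phi) * gamma / (gamma + 1j * (f - f0))
        line = line + cr + 1j * ci
        return np.concatenate([np.real(line), np.imag(line)])

    h0 = float(np.abs(freq[j]))
    theta0 = np.array([max(h0, 1e-12), float(np.angle(freq[j])),
                       float(ppm[j]), gamma0, 0.0, 0.0])
    eps = 1e-9
    bounds = (
        [0.0, -2 * np.pi, lo + eps, 0.1 * step, -np.inf, -np.inf],
        [np.inf, 2 * np.pi, hi - eps, 50.0 * gamma0, np.inf, np.inf],
    )
    theta0[2] = min(max(theta0[2], lo + 2 * eps), hi - 2 * eps)
    sol = least_squares(lambda th: model(th) - y, theta0, bounds=bounds,
                        method="trf", xtol=1e-12, ftol=1e-12)
    return float(sol.x[2])


def ph_from_spectrum(
    spectrum: Spectrum,
    reference_label: str = "PCr",
    probe_label: str = "Pi",
    calibration: PhCalibration = DEFAULT_CALIBRATION,
    snr_threshold: float = 5.0,
) -> float:
    """pH from peak positions of a spectrum (reference peak, Pi probe).

    The reference peak is located near its nominal shift (PCr: 0 ppm) and
    the probe within the open calibration interval relative to it, using a
    matched-filter detector plus a local Lorentzian least-squares position
    fit (see :func:`_peak_finder`).  A peak must score ``snr_threshold``
    standard deviations above the matched-filtered noise floor to count as
    detected; missing peaks raise :class:`PeakNotFoundError` naming the
    signal.
    """
    if reference_label not in _REFERENCE_SHIFTS:
        raise ValidationError(
            f"unsupported reference peak '{reference_label}'; "
            f"supported: {sorted(_REFERENCE_SHIFTS)}")
    locate = _peak_finder(spectrum)
    ref_nominal = _REFERENCE_SHIFTS[reference_label]
    ref_ppm = locate(ref_nominal - _SEARCH_HALFWIDTH,
                     ref_nominal + _SEARCH_HALFWIDTH, snr_threshold,
                     reference_label)
    margin = 0.05  # keep away from the singular calibration bounds
    probe_ppm = locate(ref_ppm + calibration.delta_acid + margin,
                       ref_ppm + calibration.delta_base - margin,
                       snr_threshold, probe_label)
    return ph_from_shift(probe_ppm - ref_ppm, calibration)
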