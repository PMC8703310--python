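"""Seeded phantom-like and tissue-like ³¹P spectrum generation.

Presets carry a ground-truth record so recovery tests can check any stage of
the pipeline.  SNR is defined as the tallest clean-spectrum peak magnitude
divided by the frequency-domain noise SD per real/imaginary component; with
i.i.d. complex time-domain noise of per-component SD σ_t and an N-point DFT
that SD equals σ_t·√N, so σ_t = peak / (snr·√N).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .ph import shift_from_ph
from .registry import Registry, load_registry
from .simulation import (
    MP_BROADENING_FACTOR,
    SpectralAxis,
    Spectrum,
    make_axis,
    simulate_signal,
)

__all__ = [
    "TissuePreset",
    "muscle_preset",
    "liver_preset",
    "phantom_preset",
    "generate",
    "default_tissue_axis",
]

#: relative signal intensities over the six-signal reporting subset
_MUSCLE_TRUTH = {"gATP": 12.4, "aATP": 10.3, "bATP": 10.0,
                 "GPC": 2.6, "PCr": 60.2, "Pi": 4.4}
_LIVER_TRUTH = {"gATP": 23.3, "aATP": 26.9, "bATP": 13.4,
                "GPC": 21.6, "PCr": 2.5, "Pi": 12.3}
#: qualitative extras for demo-style "rich" liver spectra (non-quantitative)
_LIVER_RICH_EXTRAS = {"PE": 3.0, "PC": 3.0, "GPE": 4.0, "PtdC": 2.0,
                      "MP": 5.0, "NADH": 1.0, "NAD+": 1.5,
                      "UDPG_rib": 1.0, "UDPG_glc": 1.0}


@dataclass(frozen=True)
class TissuePreset:
    name: str
    ground_truth: Mapping[str, float]   # signal label -> relative amplitude
    ph: float = 7.0
    linewidth_hz: float = 5.0
    snr: float | None = 50.0            # None => noiseless
    decoupled: bool = True
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.ground_truth.values()):
            raise ValidationError("ground-truth amplitudes must be >= 0")
        if not (5.5 < self.ph < 8.5):
            raise ValidationError("preset pH must lie in (5.5, 8.5)")


def default_tissue_axis() -> SpectralAxis:
    """2048 points over 2000 Hz at 49.9 MHz: covers −20…+20 ppm."""
    return make_axis(2048, 2000.0, 49.9)


def muscle_preset(ph: float = 7.0, snr: float | None = 50.0,
                  linewidth_hz: float = 5.0) -> TissuePreset:
    return TissuePreset("muscle", dict(_MUSCLE_TRUTH), ph=ph,
                        linewidth_hz=linewidth_hz, snr=snr)


def liver_preset(ph: float = 7.0, snr: float | None = 50.0,
                 linewidth_hz: float = 15.0, rich: bool = False) -> TissuePreset:
    truth = dict(_LIVER_TRUTH)
    extras = {}
    if rich:
        truth.update(_LIVER_RICH_EXTRAS)
        extras["rich"] = True  # extra weights are qualitative, not quantitative
    return TissuePreset("liver", truth, ph=ph, linewidth_hz=linewidth_hz,
                        snr=snr, extras=extras)


def phantom_preset(metabolite: str, ph: float = 7.0, snr: float | None = None,
                   linewidth_hz: float = 1.0,
                   registry: Registry | None = None) -> TissuePreset:
    """Single-metabolite phantom: metabolite + PCr standard + phosphate buffer.

    Amplitudes are proportional to concentration × one ³¹P nucleus per
    signal: metabolite 10 mM (2 mM for the reduced-concentration UDPG and
    2,3-DPG phantoms, whose buffer is 10 mM instead of 40 mM), PCr 5 mM,
    Pi from the buffer.
    """
    reg = registry or load_registry()
    entry = reg[metabolite]
    if entry.phantom_concentration is None:
        raise ValidationError(
            f"'{metabolite}' is a literature-only entry without phantom data")
    reduced = metabolite in ("UDPG", "DPG23")
    truth: dict[str, float] = {}
    for comp in entry.components:
        truth[comp.label] = float(entry.phantom_concentration)
    if metabolite != "PCr":
        truth["PCr"] = 5.0
    if metabolite != "Pi":
        truth["Pi"] = 10.0 if reduced else 40.0
    return TissuePreset(f"phantom:{metabolite}", truth, ph=ph,
                        linewidth_hz=linewidth_hz, snr=snr)


def _component_shift(reg: Registry, label: str, ph: float) -> float:
    _, comp = reg.component(label)
    if label == "Pi":
        return shift_from_ph(ph)
    if comp.shift_basisp is not None:
        return comp.shift_basisp
    return comp.shift("ph70")  # non-basis signals (ADP) fall back to phantom data


def generate(
    preset: TissuePreset,
    axis: SpectralAxis | None = None,
    seed: int | None = None,
    registry: Registry | None = None,
) -> tuple[Spectrum, dict]:
    """Generate a spectrum for ``preset`` plus its ground-truth record.

    Signals are placed at the basis shifts (Pi overridden through the pH
    calibration), share the preset linewidth (MP broadened by the standard
    factor), and are summed with the preset amplitudes; seeded complex
    Gaussian noise is scaled to the preset SNR.
    """
    reg = registry or load_registry()
    axis = axis or default_tissue_axis()
    fid = np.zeros(axis.n_points, dtype=complex)
    shifts: dict[str, float] = {}
    for label, amp in preset.ground_truth.items():
        _, comp = reg.component(label)
        shift = _component_shift(reg, label, preset.ph)
        width = preset.linewidth_hz * (MP_BROADENING_FACTOR if label == "MP" else 1.0)
        shifted = replace(comp, shift_basisp=shift)
        spec = simulate_signal(shifted, axis, variant="basisp",
                               decoupled=preset.decoupled,
                               fwhm_hz=width, amplitude=amp)
        fid += spec.fid
        shifts[label] = shift

    clean_peak = float(np.max(np.abs(Spectrum.from_fid(axis, fid).freq)))
    noise_sd_t = 0.0
    if preset.snr is not None and preset.snr > 0:
        noise_sd_t = clean_peak / (preset.snr * np.sqrt(axis.n_points))
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd_t, (axis.n_points, 2))
        fid = fid + noise[:, 0] + 1j * noise[:, 1]

    spectrum = Spectrum.from_fid(axis, fid, provenance={
        "preset": preset.name, "seed": seed, "snr": preset.snr,
        "decoupled": preset.decoupled, "linewidth_hz": preset.linewidth_hz,
        "noise_sd_time": noise_sd_t,
    })
    truth = {
        "preset": preset.name,
        "ph": preset.ph,
        "linewidth_hz": preset.linewidth_hz,
        "snr": preset.snr,
        "seed": seed,
        "amplitudes": dict(preset.ground_truth),
        "shifts_ppm": shifts,
        "noise_sd_time": noise_sd_t,
        "noise_sd_freq": noise_sd_t * float(np.sqrt(axis.n_points)),
    }
    return spectrum, truth
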