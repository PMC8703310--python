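"""Complex FID/spectrum simulation of ³¹P multiplets and basis assembly.

Model: each spectral line is an exponentially damped complex sinusoid

    s(t) = w · A · exp(2πi f t) · exp(−π · fwhm · t)

with f the offset from the transmitter in Hz, so the frequency-domain
lineshape is Lorentzian with full width at half maximum ``fwhm``.  A
multiplet places lines at the centre shift ± k·J with binomial weights
(doublet 1:1, triplet 1:2:1); weights sum to one so the time-zero amplitude
equals the requested amplitude regardless of multiplicity.

Transform contract: the frequency-domain array is the DFT of the FID with
the first time-domain point halved (removing the rectangle-rule baseline
offset of a truncated Lorentzian), reordered so that index 0 corresponds to
the highest ppm value — the conventional right-to-left ppm display order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AxisMismatchError, ValidationError
from .registry import MultipletComponent, Registry, basis_signals

__all__ = [
    "SpectralAxis",
    "Spectrum",
    "BasisMember",
    "BasisSet",
    "make_axis",
    "to_frequency",
    "from_frequency",
    "multiplet_lines",
    "simulate_signal",
    "build_basis",
    "combine_spectra",
]

#: defaults mirroring the phantom acquisition (2048 points, 1 kHz, 3 T)
DEFAULT_N_POINTS = 2048
DEFAULT_BANDWIDTH_HZ = 1000.0
DEFAULT_LARMOR_MHZ = 49.9


@dataclass(frozen=True)
class SpectralAxis:
    """Sampling and referencing metadata defining the Hz↔ppm mapping."""

    n_points: int = DEFAULT_N_POINTS
    bandwidth_hz: float = DEFAULT_BANDWIDTH_HZ
    larmor_mhz: float = DEFAULT_LARMOR_MHZ
    reference_ppm: float = 0.0           # ppm value at the transmitter frequency
    acquisition_delay_ms: float = 0.0    # TE*; applied to simulated FIDs

    def __post_init__(self):
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.bandwidth_hz <= 0 or self.larmor_mhz <= 0:
            raise ValidationError("bandwidth and larmor frequency must be > 0")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    @property
    def ppm_span(self) -> float:
        return self.bandwidth_hz / self.larmor_mhz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, including the acquisition delay."""
        return (self.acquisition_delay_ms * 1e-3
                + np.arange(self.n_points) * self.dwell_s)

    @property
    def hz(self) -> np.ndarray:
        """Frequency offsets (Hz) in spectrum order (decreasing)."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_points, self.dwell_s))
        return f[::-1].copy()

    @property
    def ppm(self) -> np.ndarray:
        """ppm grid in spectrum order (monotonically decreasing)."""
        return self.reference_ppm + self.hz / self.larmor_mhz

    def ppm_to_hz(self, ppm: float) -> float:
        return (ppm - self.reference_ppm) * self.larmor_mhz

    def index_of_ppm(self, ppm: float) -> int:
        return int(np.argmin(np.abs(self.ppm - ppm)))

    def compatible(self, other: "SpectralAxis", rtol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and np.isclose(self.bandwidth_hz, other.bandwidth_hz, rtol=rtol)
            and np.isclose(self.larmor_mhz, other.larmor_mhz, rtol=rtol)
            and np.isclose(self.reference_ppm, other.reference_ppm, atol=1e-9)
        )


def make_axis(
    n_points: int = DEFAULT_N_POINTS,
    bandwidth_hz: float = DEFAULT_BANDWIDTH_HZ,
    larmor_mhz: float = DEFAULT_LARMOR_MHZ,
    reference_ppm: float = 0.0,
    acquisition_delay_ms: float = 0.0,
) -> SpectralAxis:
    """Construct a :class:`SpectralAxis` (validates its arguments)."""
    return SpectralAxis(n_points, bandwidth_hz, larmor_mhz, reference_ppm,
                        acquisition_delay_ms)


def to_frequency(fid: np.ndarray) -> np.ndarray:
    """FID → spectrum under the module transform contract (see module docs)."""
    x = np.asarray(fid, dtype=complex).copy()
    x[0] *= 0.5
    return np.fft.fftshift(np.fft.fft(x))[::-1].copy()


def from_frequency(freq: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_frequency`."""
    x = np.fft.ifft(np.fft.ifftshift(np.asarray(freq, dtype=complex)[::-1]))
    x[0] *= 2.0
    return x


@dataclass(frozen=True)
class Spectrum:
    """A complex signal bound to an axis, in both domains."""

    axis: SpectralAxis
    fid: np.ndarray
    freq: np.ndarray
    provenance: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_fid(cls, axis: SpectralAxis, fid: np.ndarray,
                 provenance: Mapping[str, object] | None = None) -> "Spectrum":
        fid = np.asarray(fid, dtype=complex)
        if fid.shape != (axis.n_points,):
            raise ValidationError(
                f"FID length {fid.shape} does not match axis n_points={axis.n_points}")
        return cls(axis=axis, fid=fid, freq=to_frequency(fid),
                   provenance=dict(provenance or {}))

    @classmethod
    def from_freq(cls, axis: SpectralAxis, freq: np.ndarray,
                  provenance: Mapping[str, object] | None = None) -> "Spectrum":
        freq = np.asarray(freq, dtype=complex)
        if freq.shape != (axis.n_points,):
            raise ValidationError(
                f"spectrum length {freq.shape} does not match axis n_points={axis.n_points}")
        return cls(axis=axis, fid=from_frequency(freq), freq=freq,
                   provenance=dict(provenance or {}))


def multiplet_lines(component: MultipletComponent,
                    decoupled: bool) -> list[tuple[float, float]]:
    """(offset_hz, weight) pairs of the resolved lines; weights sum to 1."""
    n = component.n_lines(decoupled)
    if n == 1:
        return [(0.0, 1.0)]
    j = float(component.j_coupling)
    if n == 2:
        return [(-j / 2.0, 0.5), (j / 2.0, 0.5)]
    return [(-j, 0.25), (0.0, 0.5), (j, 0.25)]


def simulate_signal(
    component: MultipletComponent,
    axis: SpectralAxis,
    variant: str = "basisp",
    decoupled: bool = True,
    fwhm_hz: float = 1.0,
    amplitude: float = 1.0,
) -> Spectrum:
    """Simulate one metabolite signal as a sum of damped complex sinusoids."""
    if fwhm_hz <= 0:
        raise ValidationError("fwhm_hz must be > 0")
    center_ppm = component.shift(variant)
    f0 = axis.ppm_to_hz(center_ppm)
    t = axis.times
    fid = np.zeros(axis.n_points, dtype=complex)
    for off, w in multiplet_lines(component, decoupled):
        fid += w * amplitude * np.exp((2j * np.pi * (f0 + off) - np.pi * fwhm_hz) * t)
    return Spectrum.from_fid(axis, fid, provenance={
        "label": component.label, "variant": variant, "shift_ppm": center_ppm,
        "decoupled": decoupled, "fwhm_hz": fwhm_hz, "amplitude": amplitude,
    })


@dataclass(frozen=True)
class BasisMember:
    label: str
    spectrum: Spectrum
    shift_ppm: float
    fwhm_hz: float
    entry_abbrev: str


@dataclass(frozen=True)
class BasisSet:
    axis: SpectralAxis
    members: tuple[BasisMember, ...]
    decoupled: bool
    fwhm_hz: float
    registry_version: str

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.members]

    def member(self, label: str) -> BasisMember:
        for m in self.members:
            if m.label == label:
                return m
        raise KeyError(f"no basis member labeled '{label}'")


#: default line-broadening multiplier for the broad MP background resonance
MP_BROADENING_FACTOR = 5.0


def build_basis(
    registry: Registry,
    axis: SpectralAxis,
    decoupled: bool = True,
    fwhm_hz: float = 1.0,
    overrides: Mapping[str, float] | None = None,
    include: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
) -> BasisSet:
    """Simulate one model spectrum per basis-eligible signal.

    Members use the ``basisp`` shift variant and unit amplitude; the MP
    background uses a broad lineshape (``MP_BROADENING_FACTOR × fwhm_hz``)
    unless overridden.  The acquisition delay is forced to zero so basis
    members carry no delay-induced first-order phase.
    """
    overrides = dict(overrides or {})
    basis_axis = replace(axis, acquisition_delay_ms=0.0)
    members = []
    for entry, comp in basis_signals(registry, include=include, exclude=exclude):
        width = overrides.get(
            comp.label,
            fwhm_hz * MP_BROADENING_FACTOR if comp.label == "MP" else fwhm_hz)
        spec = simulate_signal(comp, basis_axis, variant="basisp",
                               decoupled=decoupled, fwhm_hz=width, amplitude=1.0)
        members.append(BasisMember(
            label=comp.label, spectrum=spec, shift_ppm=comp.shift_basisp,
            fwhm_hz=width, entry_abbrev=entry.abbrev))
    return BasisSet(axis=basis_axis, members=tuple(members), decoupled=decoupled,
                    fwhm_hz=fwhm_hz, registry_version=registry.version)


def combine_spectra(
    spectra: Sequence[Spectrum],
    weights: Sequence[float] | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> Spectrum:
    """Weighted complex time-domain sum, with optional seeded Gaussian noise.

    ``noise_sd`` is the standard deviation per real/imaginary component of
    each time-domain point.
    """
    if not spectra:
        raise ValidationError("combine_spectra requires at least one spectrum")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if not axis.compatible(s.axis):
            raise AxisMismatchError("spectra do not share a common axis")
    if weights is None:
        weights = [1.0] * len(spectra)
    if len(weights) != len(spectra):
        raise ValidationError("weights length must match spectra length")
    fid = np.zeros(axis.n_points, dtype=complex)
    for w, s in zip(weights, spectra):
        fid = fid + w * s.fid
    prov: dict[str, object] = {"combined": len(spectra)}
    if noise_sd:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, (axis.n_points, 2))
        fid = fid + noise[:, 0] + 1j * noise[:, 1]
        prov.update(noise_sd=float(noise_sd), seed=seed)
    return Spectrum.from_fid(axis, fid, provenance=prov)
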