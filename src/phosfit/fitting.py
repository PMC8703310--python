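"""Frequency-domain linear-combination fitting with CRLB reporting.

The measured complex spectrum is modeled on a fit window as

    S(ν) ≈ e^{i φ(ν)} · Σ_m a_m · B_m(ν; Δ_m, g)  +  baseline(ν)

where ``B_m`` is basis member *m* frequency-shifted by Δ_m ppm and
Lorentzian-broadened by ``g`` Hz (one global broadening), φ(ν) is a zero- +
first-order phase in degrees and degrees/ppm, and the baseline is a
penalized cubic-spline expansion per real/imaginary channel.  Amplitudes and
baseline coefficients are solved by (optionally nonnegativity-constrained)
linear least squares inside each evaluation of the outer nonlinear problem
over (phases, broadening, shifts) — a separable / variable-projection
scheme.  Zero-order phase, first-order phase, and per-signal shifts carry
Gaussian priors weighted by the estimated noise level, so the priors vanish
for noiseless data.

The fit is deterministic: fixed initialization (shifts 0, phases at the
prior means, broadening from the tallest-peak width), no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import least_squares, lsq_linear

from .errors import AxisMismatchError, ValidationError
from .simulation import BasisSet, Spectrum, to_frequency

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_spectrum",
    "estimate_crlb",
    "relative_intensities",
    "compare_methods",
    "grade_cv",
    "DEFAULT_REPORT_SUBSET",
]

#: the six prominent signals conventionally reported for muscle/liver
DEFAULT_REPORT_SUBSET = ("gATP", "aATP", "bATP", "GPC", "PCr", "Pi")


@dataclass(frozen=True)
class FitConfig:
    """Control parameters of the linear-combination fit."""

    shift_sd: float = 0.01                      # ppm, prior SD per signal shift
    phase0_prior: tuple[float, float] = (-96.0, 10.0)   # degrees (mean, SD)
    phase1_prior: tuple[float, float] = (7.0, 4.0)      # degrees/ppm (mean, SD)
    reference_peak: str = "PCr"                 # pinned at zero shift adjustment
    baseline_enabled: bool = True
    baseline_knot_spacing: float = 99.0         # ppm; 99 => effectively rigid
    baseline_penalty_bounds: tuple[float, float] = (7.8e-10, 3.9e-7)
    broadening_max: float = 100.0               # Hz
    fit_window: tuple[float, float] = (-20.0, 10.0)     # ppm, clipped to axis
    amplitude_nonneg: bool = True
    noise_window: tuple[float, float] = (12.0, 18.0)    # ppm, signal-free region
    shift_bound: float = 0.2                    # ppm, hard bound on adjustments
    max_iter: int = 200

    def __post_init__(self):
        if self.shift_sd <= 0 or self.phase0_prior[1] <= 0 or self.phase1_prior[1] <= 0:
            raise ValidationError("prior SDs must be > 0")
        if self.baseline_knot_spacing <= 0:
            raise ValidationError("baseline_knot_spacing must be > 0")
        if self.fit_window[0] >= self.fit_window[1]:
            raise ValidationError("fit_window must be a nonempty interval")


@dataclass
class FitResult:
    labels: list[str]
    amplitudes: np.ndarray            # per signal, >= 0 under the default config
    shifts: np.ndarray                # ppm adjustment per signal (reference: 0)
    broadening: float                 # Hz, global extra Lorentzian width
    phase0: float                     # degrees
    phase1: float                     # degrees/ppm
    baseline: np.ndarray              # complex baseline evaluated on the window
    baseline_coefs: np.ndarray        # stacked real/imag spline coefficients
    residual: np.ndarray              # complex (data - model) on the window
    window_ppm: np.ndarray
    noise_sd: float                   # per real/imag frequency-domain component
    relative_intensity: dict[str, float]
    relative_crlb: dict[str, float]   # percent; NaN where unavailable
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


class _Problem:
    def __init__(self, spectrum: Spectrum, basis: BasisSet, config: FitConfig):
        axis = spectrum.axis
        if not axis.compatible(basis.axis):
            raise AxisMismatchError(
                "spectrum and basis axes differ (n_points/bandwidth/larmor)")
        self.config = config
        self.axis = axis
        self.labels = basis.labels
        self.n_members = len(self.labels)
        if self.n_members == 0:
            raise ValidationError("basis set has no members")
        self.member_fids = np.stack([m.spectrum.fid for m in basis.members])
        self.t = axis.times - axis.acquisition_delay_ms * 1e-3  # basis built delay-free

        ppm = axis.ppm
        lo = max(config.fit_window[0], float(ppm.min()))
        hi = min(config.fit_window[1], float(ppm.max()))
        if lo >= hi:
            raise ValidationError("fit window does not intersect the axis")
        self.mask = (ppm >= lo) & (ppm <= hi)
        self.ppm_w = ppm[self.mask]
        self.data_w = spectrum.freq[self.mask]
        self.n_w = len(self.ppm_w)

        # shift parameters: one per member except the pinned reference peak
        self.free_shift_idx = [i for i, lab in enumerate(self.labels)
                               if lab != config.reference_peak]

        self.noise_sd = self._estimate_noise(spectrum)
        self.baseline_design, self.penalty = self._baseline_design(lo, hi)
        self.n_bl = self.baseline_design.shape[1]  # per channel
        self.alpha = float(np.sqrt(config.baseline_penalty_bounds[0]
                                   * config.baseline_penalty_bounds[1]))

    # -- pieces ------------------------------------------------------------

    def _estimate_noise(self, spectrum: Spectrum) -> float:
        ppm = spectrum.axis.ppm
        lo, hi = self.config.noise_window
        sel = (ppm >= lo) & (ppm <= hi)
        if np.count_nonzero(sel) < 16:
            # window off-axis: fall back to the outermost bins of the spectrum
            k = max(16, spectrum.axis.n_points // 16)
            sel = np.zeros_like(sel)
            sel[:k] = True
        region = np.real(spectrum.freq[sel])
        x = np.arange(region.size, dtype=float)
        trend = np.polynomial.polynomial.polyvander(x, 1)
        coef, *_ = np.linalg.lstsq(trend, region, rcond=None)
        return float(np.std(region - trend @ coef))

    def _baseline_design(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        if not self.config.baseline_enabled:
            return np.zeros((self.n_w, 0)), np.zeros((0, 0))
        spacing = self.config.baseline_knot_spacing
        interior = np.arange(lo + spacing, hi - 1e-9, spacing)
        knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        ncoef = len(interior) + 4
        x = np.clip(self.ppm_w, lo, hi - 1e-12)
        design = BSpline.design_matrix(x, knots, 3).toarray()
        if ncoef >= 3:
            d2 = (np.diff(np.eye(ncoef), n=2, axis=0))
        else:
            d2 = np.zeros((0, ncoef))
        return design, d2

    def columns(self, shifts: np.ndarray, broad: float) -> np.ndarray:
        """Complex member columns on the window for given shifts (ppm) and
        extra broadening (Hz)."""
        df = shifts * self.axis.larmor_mhz  # Hz
        mod = np.exp((2j * np.pi * df[:, None] - np.pi * max(broad, 0.0))
                     * self.t[None, :])
        fids = self.member_fids * mod
        fids[:, 0] *= 0.5
        spec = np.fft.fftshift(np.fft.fft(fids, axis=1), axes=1)[:, ::-1]
        return spec[:, self.mask].T  # (n_w, n_members)

    def design(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Stacked real design matrix and data vector for outer params ``z``.

        z = [phase0_deg, phase1_deg_per_ppm, broadening_hz, free shifts...].
        Column order: amplitudes, baseline-real coefs, baseline-imag coefs.
        """
        phase0, phase1, broad = z[0], z[1], z[2]
        shifts = np.zeros(self.n_members)
        shifts[self.free_shift_idx] = z[3:]
        cols = self.columns(shifts, broad)
        phase = np.exp(1j * np.deg2rad(phase0 + phase1 * self.ppm_w))
        phased = cols * phase[:, None]
        nb = self.n_bl
        a = np.zeros((2 * self.n_w, self.n_members + 2 * nb))
        a[: self.n_w, : self.n_members] = np.real(phased)
        a[self.n_w:, : self.n_members] = np.imag(phased)
        a[: self.n_w, self.n_members: self.n_members + nb] = self.baseline_design
        a[self.n_w:, self.n_members + nb:] = self.baseline_design
        b = np.concatenate([np.real(self.data_w), np.imag(self.data_w)])
        return a, b

    def _augment(self, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.penalty.shape[0] == 0 or self.alpha == 0:
            return a, b
        nb, npen = self.n_bl, self.penalty.shape[0]
        rows = np.zeros((2 * npen, a.shape[1]))
        w = math.sqrt(self.alpha)
        rows[:npen, self.n_members: self.n_members + nb] = w * self.penalty
        rows[npen:, self.n_members + nb:] = w * self.penalty
        return np.vstack([a, rows]), np.concatenate([b, np.zeros(2 * npen)])

    def solve_linear(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a_aug, b_aug = self._augment(a, b)
        x, *_ = np.linalg.lstsq(a_aug, b_aug, rcond=None)
        amps = x[: self.n_members]
        scale = max(float(np.max(np.abs(amps))), 1e-300)
        if self.config.amplitude_nonneg and np.any(amps < -1e-9 * scale):
            lb = np.full(a.shape[1], -np.inf)
            ub = np.full(a.shape[1], np.inf)
            lb[: self.n_members] = 0.0
            res = lsq_linear(a_aug, b_aug, bounds=(lb, ub), method="trf",
                             tol=1e-12)
            x = res.x
        if self.config.amplitude_nonneg:
            x[: self.n_members] = np.maximum(x[: self.n_members], 0.0)
        return x

    def prior_residuals(self, z: np.ndarray) -> np.ndarray:
        c = self.config
        sd = max(self.noise_sd, 1e-300)
        out = [
            sd * (z[0] - c.phase0_prior[0]) / c.phase0_prior[1],
            sd * (z[1] - c.phase1_prior[0]) / c.phase1_prior[1],
        ]
        out.extend(sd * z[3:] / c.shift_sd)
        return np.asarray(out)

    def residuals(self, z: np.ndarray) -> np.ndarray:
        a, b = self.design(z)
        x = self.solve_linear(a, b)
        return np.concatenate([b - a @ x, self.prior_residuals(z)])

    def approx_cost(self, z: np.ndarray) -> float:
        """Cheap penalized cost for basin selection: unconstrained linear
        solve with negative amplitudes clipped to zero."""
        a, b = self.design(z)
        a_aug, b_aug = self._augment(a, b)
        x, *_ = np.linalg.lstsq(a_aug, b_aug, rcond=None)
        if self.config.amplitude_nonneg:
            x[: self.n_members] = np.maximum(x[: self.n_members], 0.0)
        r = b - a @ x
        p = self.prior_residuals(z)
        return float(r @ r + p @ p)

    def initial_phases(self, broad0: float) -> tuple[float, float]:
        """Deterministic coarse grid over (phase0, phase1) picking the basin
        with the lowest penalized cost; phases at the prior means alone are a
        local-minimum trap when the data phase is far from the priors."""
        c = self.config
        p1_mean, p1_sd = c.phase1_prior
        best = (math.inf, c.phase0_prior[0], p1_mean)
        nshift = len(self.free_shift_idx)
        for p0 in range(-180, 180, 30):
            for p1 in (p1_mean - 2 * p1_sd, p1_mean, p1_mean + 2 * p1_sd):
                z = np.concatenate([[p0, p1, broad0], np.zeros(nshift)])
                cost = self.approx_cost(z)
                if cost < best[0]:
                    best = (cost, float(p0), float(p1))
        return best[1], best[2]

    def initial_broadening(self) -> float:
        """FWHM of the tallest data peak minus the basis width, floored at 0."""
        mag = np.abs(self.data_w)
        k = int(np.argmax(mag))
        half = mag[k] / 2.0
        left = k
        while left > 0 and mag[left] > half:
            left -= 1
        right = k
        while right < len(mag) - 1 and mag[right] > half:
            right += 1
        dhz = self.axis.bandwidth_hz / self.axis.n_points
        width = (right - left) * dhz
        return max(width - 1.0, 0.0)


def fit_spectrum(spectrum: Spectrum, basis: BasisSet,
                 config: FitConfig | None = None) -> FitResult:
    """Fit ``spectrum`` as a linear combination of ``basis`` members.

    Returns a :class:`FitResult` carrying amplitudes, shifts, phases,
    baseline, residual, relative intensities over the standard reporting
    subset, and relative CRLBs.  Non-convergence is flagged in
    ``diagnostics['converged']``, never silent.
    """
    config = config or FitConfig()
    prob = _Problem(spectrum, basis, config)

    broad0 = prob.initial_broadening()
    phase0_init, phase1_init = prob.initial_phases(broad0)
    z0 = np.concatenate([
        [phase0_init, phase1_init, broad0],
        np.zeros(len(prob.free_shift_idx)),
    ])
    lb = np.concatenate([[-np.inf, -np.inf, 0.0],
                         -config.shift_bound * np.ones(len(prob.free_shift_idx))])
    ub = np.concatenate([[np.inf, np.inf, config.broadening_max],
                         config.shift_bound * np.ones(len(prob.free_shift_idx))])
    x_scale = np.concatenate([[10.0, 2.0, 1.0],
                              np.full(len(prob.free_shift_idx), config.shift_sd)])
    sol = least_squares(
        prob.residuals, z0, bounds=(lb, ub), x_scale=x_scale,
        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=config.max_iter * (len(z0) + 1),
        method="trf",
    )

    z = sol.x
    a, b = prob.design(z)
    x = prob.solve_linear(a, b)
    amps = x[: prob.n_members]
    nb = prob.n_bl
    bl_coefs = x[prob.n_members:]
    baseline = (prob.baseline_design @ bl_coefs[:nb]
                + 1j * (prob.baseline_design @ bl_coefs[nb:]))
    model = a @ x
    resid = b - model
    resid_c = resid[: prob.n_w] + 1j * resid[prob.n_w:]
    shifts = np.zeros(prob.n_members)
    shifts[prob.free_shift_idx] = z[3:]

    # post-fit noise: residual in the signal-free window when available,
    # else the pre-fit estimate
    noise_sd = prob.noise_sd if prob.noise_sd > 0 else float(np.std(resid))

    result = FitResult(
        labels=list(prob.labels),
        amplitudes=amps,
        shifts=shifts,
        broadening=float(z[2]),
        phase0=float(z[0]),
        phase1=float(z[1]),
        baseline=baseline,
        baseline_coefs=bl_coefs,
        residual=resid_c,
        window_ppm=prob.ppm_w.copy(),
        noise_sd=noise_sd,
        relative_intensity={},
        relative_crlb={},
        diagnostics={
            "converged": bool(sol.status > 0),
            "status": int(sol.status),
            "message": sol.message,
            "nfev": int(sol.nfev),
            "cost": float(sol.cost),
            "baseline_alpha": prob.alpha,
        },
    )
    subset = [lab for lab in DEFAULT_REPORT_SUBSET if lab in result.labels]
    if not subset:
        subset = list(result.labels)
    result.relative_intensity = relative_intensities(result, subset)
    result.relative_crlb = estimate_crlb(result, basis, config)
    return result


def estimate_crlb(fit: FitResult, basis: BasisSet, config: FitConfig | None = None,
                  noise_sd: float | None = None) -> dict[str, float]:
    """Relative Cramér–Rao lower bounds (percent) of the fitted amplitudes.

    Fisher information is assembled from the model partial derivatives with
    respect to all free parameters (amplitudes, free shifts, broadening,
    both phases, baseline coefficients) over the stacked real/imaginary
    channels, scaled by the noise variance.  Amplitudes at the nonnegativity
    boundary are reported as NaN (unavailable).
    """
    config = config or FitConfig()
    sigma = fit.noise_sd if noise_sd is None else noise_sd
    if sigma <= 0:
        raise ValidationError("CRLB requires a positive noise_sd")
    # rebuild the design machinery around the fitted parameters
    prob = _Problem(
        Spectrum.from_freq(basis.axis, np.zeros(basis.axis.n_points, dtype=complex)),
        basis, config)
    z = np.concatenate([[fit.phase0, fit.phase1, fit.broadening],
                        fit.shifts[prob.free_shift_idx]])
    a, _ = prob.design(z)
    lin = np.concatenate([fit.amplitudes, fit.baseline_coefs])

    cols = [a]  # analytic: amplitudes + baseline coefficients
    # numeric central differences for the nonlinear parameters
    steps = np.concatenate([[1e-3, 1e-4, 1e-4],
                            np.full(len(prob.free_shift_idx), 1e-6)])
    for j, h in enumerate(steps):
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        ap, _ = prob.design(zp)
        am, _ = prob.design(zm)
        cols.append(((ap - am) @ lin)[:, None] / (2 * h))
    jac = np.hstack(cols)
    # fold the Gaussian priors on phases and shifts into the information
    # matrix (the estimator uses them, so the bound must too): appending a
    # row sigma/sigma_prior at a parameter's column adds 1/sigma_prior^2 to
    # the Fisher matrix after the 1/sigma^2 scaling below
    n_lin = len(fit.labels) + len(fit.baseline_coefs)
    prior_sds = [config.phase0_prior[1], config.phase1_prior[1], None] + \
        [config.shift_sd] * len(prob.free_shift_idx)
    prior_rows = []
    for j, psd in enumerate(prior_sds):
        if psd is None:
            continue
        row = np.zeros(jac.shape[1])
        row[n_lin + j] = sigma / psd
        prior_rows.append(row)
    if prior_rows:
        jac = np.vstack([jac, prior_rows])
    # column-normalize before inversion: parameter scales span many orders of
    # magnitude and would otherwise dominate the condition number
    norms = np.linalg.norm(jac, axis=0)
    norms[norms == 0] = 1.0
    js = jac / norms
    fisher_s = js.T @ js
    singular = False
    try:
        cov_s = np.linalg.inv(fisher_s)
        if np.linalg.cond(fisher_s) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_s = np.linalg.pinv(fisher_s)
        singular = True
    if singular:
        fit.diagnostics["crlb_singular_fisher"] = True
    cov_diag = np.diag(cov_s) / norms**2 * sigma**2

    out: dict[str, float] = {}
    var = cov_diag[: len(fit.labels)]
    amp_floor = 1e-9 * max(float(np.max(fit.amplitudes)), 1e-300)
    for m, lab in enumerate(fit.labels):
        amp = fit.amplitudes[m]
        if amp <= amp_floor:  # at (or numerically at) the constraint boundary
            out[lab] = math.nan
        else:
            out[lab] = 100.0 * math.sqrt(max(var[m], 0.0)) / amp
    return out


def relative_intensities(fit: FitResult,
                         subset: Sequence[str] | None = None) -> dict[str, float]:
    """Percent amplitude shares over ``subset`` (sums to 100)."""
    subset = list(subset) if subset is not None else \
        [lab for lab in DEFAULT_REPORT_SUBSET if lab in fit.labels]
    if not subset:
        raise ValidationError("relative_intensities requires a nonempty subset")
    idx = {}
    for lab in subset:
        if lab not in fit.labels:
            raise ValidationError(f"label '{lab}' not present in fit")
        idx[lab] = fit.labels.index(lab)
    total = float(sum(fit.amplitudes[i] for i in idx.values()))
    if total <= 0:
        raise ValidationError("subset amplitudes sum to zero")
    return {lab: 100.0 * float(fit.amplitudes[i]) / total for lab, i in idx.items()}


def grade_cv(cv: float) -> str:
    """Four-level agreement grade for a coefficient of variation (percent)."""
    if cv < 10.0:
        return "very good"
    if cv <= 20.0:
        return "good"
    if cv <= 30.0:
        return "acceptable"
    return "not acceptable"


def compare_methods(
    results_a: Sequence[Mapping[str, float]],
    results_b: Sequence[Mapping[str, float]],
) -> dict[str, dict[str, object]]:
    """Per-signal mean CV (percent) between paired relative intensities.

    ``results_a``/``results_b`` are equal-length lists of per-spectrum
    ``label → relative intensity`` mappings from two quantification methods.
    For each spectrum and signal the two paired values give
    CV = 100·(|a−b|/√2)/mean (sample SD with n = 2); the mean CV across
    spectra is graded on the four-level scale.
    """
    if len(results_a) != len(results_b):
        raise ValidationError("paired result lists must have equal length")
    if not results_a:
        raise ValidationError("empty result lists")
    labels = list(results_a[0].keys())
    for ra, rb in zip(results_a, results_b):
        if set(ra) != set(labels) or set(rb) != set(labels):
            raise ValidationError("result label sets do not match across methods")
    out = {}
    for lab in labels:
        cvs = []
        for ra, rb in zip(results_a, results_b):
            va, vb = float(ra[lab]), float(rb[lab])
            mean = 0.5 * (va + vb)
            sd = abs(va - vb) / math.sqrt(2.0)
            cvs.append(0.0 if mean == 0 else 100.0 * sd / mean)
        mean_cv = float(np.mean(cvs))
        out[lab] = {"mean_cv": mean_cv, "grade": grade_cv(mean_cv)}
    return out
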