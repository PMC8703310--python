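# phosfit

A toolkit for quantitative in vivo ³¹P magnetic resonance spectroscopy at
3 T, built around a compiled-in registry of phosphorus metabolite chemical
shifts, multiplicities and J-couplings:

- **`phosfit.registry`** — typed, queryable table of 17 metabolites
  (PCr, Pi, ATP, ADP, PE, PC, G1P, G6P, PEP, PtdC, GPC, 2,3-DPG, NADH,
  NAD⁺, UDPG, MP, GPE) with shift variants for pH 7.0 / pH 7.5 phantoms,
  in vivo positions, and the fitting-basis values; selection rules yield a
  20-signal basis (ADP excluded as fully overlapped by α/γ-ATP; ATP
  contributes three independent signals).
- **`phosfit.simulation`** — complex FID/spectrum simulation of Lorentzian
  multiplets (binomial line weights, ¹H-decoupling collapse of P–H
  multiplets, persistence of P–P couplings) and basis-set assembly on a
  configurable spectral axis.
- **`phosfit.ph`** — Henderson–Hasselbalch pH from the Pi–PCr shift
  difference, pH = 6.75 + log₁₀((δ−3.27)/(5.63−δ)), its closed-form
  inverse, and a peak-detecting pH reader for whole spectra.
- **`phosfit.fitting`** — frequency-domain linear-combination fitting with
  per-signal shift priors, zero/first-order phase priors, one global
  Lorentzian broadening, penalized-spline baseline, nonnegative amplitudes,
  relative Cramér–Rao lower bounds, relative intensities, and a CV-based
  two-method agreement grader.
- **`phosfit.synthetic`** — seeded phantom-like (metabolite + 5 mM PCr
  standard + phosphate buffer) and muscle/liver-like spectrum generators
  with exact ground-truth records for recovery testing.
- **`phosfit.io` / `phosfit.cli`** — jMRUI-style text and JSON spectrum
  containers, a namelist-style basis export, fit reports, and the `phosfit`
  command-line tool.

## Command line

```sh
# export the default decoupled basis plus a summary of shifts used
phosfit basis --out basis.txt --summary basis_summary.tsv

# generate a synthetic muscle spectrum at SNR 50 with known ground truth
phosfit simulate --preset muscle --seed 1 --out-dir run1/

# fit it with a matching six-signal basis and write a JSON/TSV report
phosfit fit --spectrum run1/spectrum.txt --out run1/fit.json \
    --table run1/fit.tsv --include ATP --include GPC --include PCr --include Pi

# pH from a shift difference or from a spectrum file
phosfit ph --shift 4.78
phosfit ph --spectrum run1/spectrum.txt

# grade the agreement between two methods' relative intensities
phosfit compare --a methodA.json --b methodB.json
```

All commands exit nonzero with a one-line diagnostic on error, and
`simulate` records a serializable run configuration whose hash plus seed
reproduces the output bit-identically.

## Notes

- The frequency-domain arrays follow the spectroscopic display convention:
  index 0 is the highest ppm value. The transform halves the first FID point
  so a Lorentzian FID yields an offset-free absorption spectrum.
- The fitter is a separable (variable-projection) nonlinear least-squares
  scheme: amplitudes and baseline coefficients are solved by constrained
  linear least squares inside every evaluation of the outer problem over
  phases, broadening and shifts. It is deterministic; initialization uses a
  coarse, fixed phase grid rather than randomness.
- Reported CRLBs include the Gaussian priors the estimator itself uses, so
  Monte-Carlo scatter matches the reported bounds.
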