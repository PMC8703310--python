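"""Spectrum/basis/report file formats and run configuration.

Spectrum text dialect (jMRUI-style): a plain-text header of ``Key: value``
lines followed by two whitespace-separated columns of real/imaginary FID
points.  Required keys: ``PointsInDataset``, ``SamplingInterval`` (ms) and
``TransmitterFrequency`` (Hz); optional: ``ReferencePpm``,
``AcquisitionDelay`` (ms).  Parsing is strict — malformed input raises
:class:`~phosfit.errors.ParseError` naming the line and field, never partial
data.

The JSON container mirrors the same information with explicit axis metadata
and a provenance block.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParseError, ValidationError
from .fitting import FitConfig, FitResult
from .simulation import BasisSet, SpectralAxis, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_basis_lcmodel",
    "read_basis_lcmodel",
    "write_basis_jmrui",
    "fit_report",
    "write_fit_report",
    "RunConfig",
]

_HEADER_KEYS = {
    "PointsInDataset": ("n_points", int),
    "SamplingInterval": ("sampling_interval_ms", float),
    "TransmitterFrequency": ("transmitter_hz", float),
    "ReferencePpm": ("reference_ppm", float),
    "AcquisitionDelay": ("acquisition_delay_ms", float),
}


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   fmt: str = "jmrui_text") -> None:
    path = Path(path)
    if fmt == "jmrui_text":
        path.write_text(_spectrum_to_text(spectrum))
    elif fmt == "package_json":
        path.write_text(_spectrum_to_json(spectrum))
    else:
        raise ValidationError(f"unknown spectrum format '{fmt}'")


def read_spectrum(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read a spectrum; format auto-detected from content when ``fmt`` is None."""
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        fmt = "package_json" if text.lstrip().startswith("{") else "jmrui_text"
    if fmt == "jmrui_text":
        return _spectrum_from_text(text)
    if fmt == "package_json":
        return _spectrum_from_json(text)
    raise ValidationError(f"unknown spectrum format '{fmt}'")


def _spectrum_to_text(spectrum: Spectrum) -> str:
    ax = spectrum.axis
    lines = [
        f"PointsInDataset: {ax.n_points}",
        f"SamplingInterval: {repr(ax.dwell_s * 1e3)}",
        f"TransmitterFrequency: {repr(ax.larmor_mhz * 1e6)}",
        f"ReferencePpm: {repr(ax.reference_ppm)}",
        f"AcquisitionDelay: {repr(ax.acquisition_delay_ms)}",
    ]
    for v in spectrum.fid:
        lines.append(f"{float(v.real)!r}\t{float(v.imag)!r}")
    return "\n".join(lines) + "\n"


def _spectrum_from_text(text: str) -> Spectrum:
    header: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    in_body = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = re.match(r"^([A-Za-z][A-Za-z0-9_]*)\s*:\s*(.+)$", line)
        if m and not in_body:
            key, value = m.group(1), m.group(2)
            if key not in _HEADER_KEYS:
                raise ParseError(f"unknown header key '{key}'", line=lineno, field=key)
            name, conv = _HEADER_KEYS[key]
            try:
                header[name] = conv(value)
            except ValueError:
                raise ParseError(f"cannot parse value '{value}'",
                                 line=lineno, field=key) from None
            continue
        in_body = True
        parts = line.split()
        if len(parts) != 2:
            raise ParseError("expected two columns (real imag)", line=lineno,
                             field="data")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(f"non-numeric data '{line}'", line=lineno,
                             field="data") from None
    for req in ("n_points", "sampling_interval_ms", "transmitter_hz"):
        if req not in header:
            raise ParseError(f"missing required header field '{req}'", field=req)
    n = int(header["n_points"])
    if len(rows) != n:
        raise ParseError(
            f"body holds {len(rows)} points but PointsInDataset = {n}",
            field="data")
    axis = SpectralAxis(
        n_points=n,
        bandwidth_hz=1e3 / header["sampling_interval_ms"],
        larmor_mhz=header["transmitter_hz"] / 1e6,
        reference_ppm=header.get("reference_ppm", 0.0),
        acquisition_delay_ms=header.get("acquisition_delay_ms", 0.0),
    )
    fid = np.array([r + 1j * i for r, i in rows])
    return Spectrum.from_fid(axis, fid, provenance={"source": "jmrui_text"})


def _spectrum_to_json(spectrum: Spectrum) -> str:
    ax = spectrum.axis
    doc = {
        "format": "phosfit-spectrum",
        "schema_version": 1,
        "axis": {
            "n_points": ax.n_points,
            "bandwidth_hz": ax.bandwidth_hz,
            "larmor_mhz": ax.larmor_mhz,
            "reference_ppm": ax.reference_ppm,
            "acquisition_delay_ms": ax.acquisition_delay_ms,
        },
        "fid": {
            "real": [float(v) for v in spectrum.fid.real],
            "imag": [float(v) for v in spectrum.fid.imag],
        },
        "provenance": _jsonable(spectrum.provenance),
    }
    return json.dumps(doc)


def _spectrum_from_json(text: str) -> Spectrum:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc.msg}", line=exc.lineno) from None
    if doc.get("format") != "phosfit-spectrum":
        raise ParseError("not a phosfit spectrum document", field="format")
    ax = doc["axis"]
    axis = SpectralAxis(
        n_points=int(ax["n_points"]), bandwidth_hz=float(ax["bandwidth_hz"]),
        larmor_mhz=float(ax["larmor_mhz"]),
        reference_ppm=float(ax.get("reference_ppm", 0.0)),
        acquisition_delay_ms=float(ax.get("acquisition_delay_ms", 0.0)),
    )
    re_, im = doc["fid"]["real"], doc["fid"]["imag"]
    if len(re_) != axis.n_points or len(im) != axis.n_points:
        raise ParseError("FID length does not match axis n_points", field="fid")
    fid = np.asarray(re_, dtype=float) + 1j * np.asarray(im, dtype=float)
    return Spectrum.from_fid(axis, fid, provenance=doc.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# basis exports
# ---------------------------------------------------------------------------


def write_basis_lcmodel(basis: BasisSet, path: str | Path) -> None:
    """Namelist-like basis container: global header + one block per member."""
    ax = basis.axis
    out = [
        " $SEQPAR",
        f" HZPPPM = {ax.larmor_mhz!r}",
        f" DELTAT = {ax.dwell_s!r}",
        f" NDATAB = {ax.n_points}",
        f" DECOUPLED = {'T' if basis.decoupled else 'F'}",
        " $END",
    ]
    for m in basis.members:
        out += [
            " $BASIS",
            f" METABO = '{m.label}'",
            f" PPMAPP = {m.shift_ppm!r}",
            f" FWHM = {m.fwhm_hz!r}",
            " $END",
        ]
        for v in m.spectrum.fid:
            out.append(f" {float(v.real)!r} {float(v.imag)!r}")
    Path(path).write_text("\n".join(out) + "\n")


def read_basis_lcmodel(path: str | Path) -> dict:
    """Parse the basis container back into axis parameters and member arrays."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, object] = {}
    members: list[dict] = []
    block: dict | None = None
    section = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line == "$SEQPAR":
            section = "seqpar"
            continue
        if line == "$BASIS":
            section = "basis"
            block = {"meta": {}, "points": []}
            members.append(block)
            continue
        if line == "$END":
            section = None
            continue
        if section in ("seqpar", "basis"):
            m = re.match(r"^(\w+)\s*=\s*(.+)$", line)
            if not m:
                raise ParseError("malformed namelist entry", line=lineno)
            key, value = m.group(1), m.group(2).strip().strip("'")
            target = header if section == "seqpar" else block["meta"]
            try:
                target[key] = float(value) if key not in ("METABO", "DECOUPLED") else value
            except ValueError:
                raise ParseError(f"cannot parse '{value}'", line=lineno,
                                 field=key) from None
            continue
        if block is None:
            raise ParseError("data before any $BASIS block", line=lineno)
        parts = line.split()
        if len(parts) != 2:
            raise ParseError("expected two columns (real imag)", line=lineno)
        block["points"].append(complex(float(parts[0]), float(parts[1])))
    n = int(header.get("NDATAB", 0))
    for b in members:
        if len(b["points"]) != n:
            raise ParseError(
                f"member '{b['meta'].get('METABO')}' holds {len(b['points'])} "
                f"points, expected {n}")
        b["points"] = np.asarray(b["points"])
    return {"header": header, "members": members}


def write_basis_jmrui(basis: BasisSet, directory: str | Path) -> list[Path]:
    """One jMRUI-style text file per basis member; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in basis.members:
        safe = re.sub(r"[^A-Za-z0-9_.+-]", "_", m.label)
        p = directory / f"{safe}.txt"
        write_spectrum(m.spectrum, p, fmt="jmrui_text")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------


def fit_report(fit: FitResult) -> dict:
    """Structured JSON-ready report of a fit."""
    return {
        "format": "phosfit-fit-report",
        "schema_version": 1,
        "converged": fit.converged,
        "phase0_deg": fit.phase0,
        "phase1_deg_per_ppm": fit.phase1,
        "broadening_hz": fit.broadening,
        "noise_sd": fit.noise_sd,
        "signals": [
            {
                "label": lab,
                "amplitude": float(fit.amplitudes[i]),
                "shift_ppm": float(fit.shifts[i]),
                "relative_intensity_pct": fit.relative_intensity.get(lab),
                "relative_crlb_pct": _nan_none(fit.relative_crlb.get(lab)),
            }
            for i, lab in enumerate(fit.labels)
        ],
        "diagnostics": _jsonable(fit.diagnostics),
    }


def _nan_none(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def write_fit_report(fit: FitResult, json_path: str | Path,
                     table_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(fit_report(fit), indent=1))
    if table_path is not None:
        rows = ["label\tamplitude\trelative_intensity_pct\trelative_crlb_pct\tshift_ppm"]
        for i, lab in enumerate(fit.labels):
            ri = fit.relative_intensity.get(lab)
            cr = _nan_none(fit.relative_crlb.get(lab))
            rows.append("\t".join([
                lab,
                f"{fit.amplitudes[i]:.6g}",
                "" if ri is None else f"{ri:.3f}",
                "" if cr is None else f"{cr:.3f}",
                f"{fit.shifts[i]:.5f}",
            ]))
        Path(table_path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable configuration of a CLI run; config + seed reproduce outputs."""

    n_points: int = 2048
    bandwidth_hz: float = 2000.0
    larmor_mhz: float = 49.9
    decoupled: bool = True
    basis_fwhm_hz: float = 1.0
    preset: str = "muscle"
    seed: int = 0
    snr: float | None = 50.0
    ph: float = 7.0
    fit: FitConfig = field(default_factory=FitConfig)
    verbosity: int = 0

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        fit_doc = doc.pop("fit", {})
        for key in ("phase0_prior", "phase1_prior", "baseline_penalty_bounds",
                    "fit_window", "noise_window"):
            if key in fit_doc and fit_doc[key] is not None:
                fit_doc[key] = tuple(fit_doc[key])
        return cls(fit=FitConfig(**fit_doc), **doc)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
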