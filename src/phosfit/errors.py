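"""Exception hierarchy shared across the package."""


class PhosfitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhosfitError, ValueError):
    """Invalid argument or configuration value."""


class MissingShiftError(PhosfitError, KeyError):
    """A requested chemical-shift variant is not tabulated for a signal."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return self.args[0] if self.args else ""


class UnknownMetaboliteError(PhosfitError, KeyError):
    """A metabolite or signal name does not resolve in the registry."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class AxisMismatchError(PhosfitError, ValueError):
    """Two spectra/basis objects do not share compatible axis parameters."""


class PeakNotFoundError(PhosfitError, RuntimeError):
    """An expected spectral peak could not be detected."""


class FitError(PhosfitError, RuntimeError):
    """Linear-combination fit failed structurally (not mere non-convergence)."""


class ParseError(PhosfitError, ValueError):
    """A spectrum/basis file failed strict parsing.

    Carries the 1-based line number and the offending field when known.
    """

    def __init__(self, message: str, line: int | None = None, field: str | None = None):
        self.line = line
        self.field = field
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if field is not None:
            loc.append(f"field '{field}'")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
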