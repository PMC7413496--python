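"""Exception hierarchy shared across the package."""


class FocalmetryError(Exception):
    """Base class for all package errors."""


class ValidationError(FocalmetryError, ValueError):
    """Invalid specification, configuration or argument values."""


class FormatError(FocalmetryError, ValueError):
    """Malformed on-disk data (ragged TIFF pages, bad config syntax)."""


class RangeError(FocalmetryError, ValueError):
    """A requested coordinate, depth or window falls outside valid bounds."""


class FitError(FocalmetryError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PlacementError(FocalmetryError, RuntimeError):
    """Could not place objects at the requested density."""


class EmptyResultError(FocalmetryError, RuntimeError):
    """An aggregation received no usable inputs."""
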