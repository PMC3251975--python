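"""Exception types used across the package.

All derive from :class:`ValueError` so callers may catch either the
specific class or the builtin.
"""


class GmaError(ValueError):
    """Base class for package errors."""


class FormatError(GmaError):
    """Raised for malformed raster input (wrong channel count, dtype, ...)."""


class ParameterError(GmaError):
    """Raised for invalid scalar parameters (non-positive sigma, bad family name, ...)."""


class ContractError(GmaError):
    """Raised when an operation precondition is violated (empty input, grid
    mismatch, shape mismatch, ...)."""
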