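"""Exception hierarchy shared across the package.

CLI exit-code mapping: ``ConfigurationError`` -> 2, ``NumericalError`` and
``DegenerateInputError`` -> 3, everything else propagates.
"""


class ApaHtpError(Exception):
    """Base class for package errors."""


class ConfigurationError(ApaHtpError):
    """Invalid or inconsistent user configuration."""


class DegenerateInputError(ApaHtpError):
    """Input that makes the requested computation ill-defined (all-zero
    matrix, empty region, zero-mean denominator, ...)."""


class NumericalError(ApaHtpError):
    """Runtime numerical failure (non-finite objective, singular system)."""


class FormatError(ApaHtpError):
    """Malformed on-disk container or report."""


class UnsupportedVersionError(FormatError):
    """Container written with a format version this build cannot read."""
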