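"""Exception types shared across the package."""

from __future__ import annotations


class NinocastError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(NinocastError, ValueError):
    """Raised when an input file or record set violates the expected format."""


class MissingMonthsError(NinocastError, LookupError):
    """A calendar computation required months that are absent from the series.

    Attributes
    ----------
    missing : list of (year, month) tuples that were required but absent.
    """

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class CoverageError(NinocastError, ValueError):
    """An ensemble or series does not cover the required month range."""


class RankDeficientError(NinocastError, ValueError):
    """The regression design matrix is (numerically) rank deficient."""
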