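"""Exception hierarchy for bardl.

All errors raised by the package derive from :class:`BardlError` so callers
can catch everything pipeline-related with a single clause while still
distinguishing validation problems from computation problems.
"""


class BardlError(Exception):
    """Base class for all bardl errors."""


class AlignmentError(BardlError):
    """Year vectors have gaps or member series disagree on the window."""


class DomainError(BardlError):
    """A value is outside the mathematical domain of an operation (e.g. log of a non-positive level)."""


class SizeError(BardlError):
    """A series or sample is too short for the requested operation."""


class DegenerateDataError(BardlError):
    """Zero-variance or otherwise degenerate data that breaks a regression or moment."""


class SpecificationError(BardlError):
    """An invalid model/dummy/lag specification."""


class CollinearityError(SpecificationError):
    """Rank-deficient design matrix. Carries the offending column names."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class ComparisonError(BardlError):
    """Two objects that must share a sample / alpha / spec do not."""


class ReplicationError(BardlError):
    """Bootstrap or Monte-Carlo replicate count below the allowed minimum."""


class RegenerationError(BardlError):
    """Bootstrap regeneration produced non-finite or explosive series."""


class GatingError(BardlError):
    """An operation was requested in a state where it is not defined
    (e.g. long-run causality without cointegration, I(2) input to the bounds test)."""


class ConfigError(BardlError):
    """Invalid analysis or DGP configuration."""


class FormatError(BardlError):
    """Unknown output/rendering format."""
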