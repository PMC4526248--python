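"""Exception hierarchy shared across the package."""


class GaitsyncError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GaitsyncError):
    """A table or file does not have the expected structure."""


class ValidationError(GaitsyncError):
    """An input violates a documented precondition."""


class InsufficientDataError(GaitsyncError):
    """Too few samples/steps inside the requested window."""


class DegenerateDataError(GaitsyncError):
    """Data admit no meaningful statistic (zero variance, all-zero diffs)."""


class AliasingError(GaitsyncError):
    """Sample rate too low to represent the step train."""


class EligibilityError(GaitsyncError):
    """No playlist song falls inside the tempo window.

    Carries the nearest-tempo song as ``fallback`` so a caller can degrade
    gracefully instead of aborting a session.
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback
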