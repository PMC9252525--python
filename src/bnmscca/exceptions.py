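"""Exception hierarchy shared across the package."""


class BnmsccaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BnmsccaError):
    """A file does not conform to the expected text layout."""


class ValidationError(BnmsccaError, ValueError):
    """Input violates a documented invariant (shape, partition, coding...)."""


class AlignmentError(ValidationError):
    """Subject axes of two tables do not match."""


class NumericalError(BnmsccaError):
    """A linear solve or scaling step failed numerically."""


class DegenerateWeightError(NumericalError):
    """A weight vector projects to zero and cannot be scaled to unit norm."""


class InfeasibleWindowError(ValidationError):
    """The requested sliding window does not fit into the time series."""


class InsufficientDataError(ValidationError):
    """Fewer complete observations than the statistic requires."""
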