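"""Exception hierarchy shared across the pipeline."""


class LakestreamError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LakestreamError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(LakestreamError, ValueError):
    """A parsed value violates a domain invariant."""


class InsufficientDataError(LakestreamError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateConfigurationError(LakestreamError, ValueError):
    """A landmark configuration has fewer than three landmarks."""


class UndefinedThetaError(LakestreamError, ArithmeticError):
    """All loci monomorphic across the pair: theta has a zero denominator."""


class UndefinedStandardizationError(LakestreamError, ArithmeticError):
    """Maximum attainable differentiation is non-positive."""
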