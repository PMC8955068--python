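"""Exception hierarchy shared across the package."""


class NanoformError(Exception):
    """Base class for all package errors."""


class FormatError(NanoformError):
    """A table or file does not match the expected schema."""


class ParseError(NanoformError):
    """A cell or field could not be parsed."""


class DesignError(NanoformError):
    """An experimental design cannot be constructed as requested."""


class TransformDomainError(NanoformError):
    """A response value lies outside the domain of the requested transform."""


class SingularFitError(NanoformError):
    """The model matrix is rank deficient."""


class UndefinedStatisticError(NanoformError):
    """A diagnostic statistic is undefined for the given data."""


class DataError(NanoformError):
    """Measured values violate a physical constraint."""


class EstimationError(NanoformError):
    """A parameter could not be estimated from the data provided."""
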