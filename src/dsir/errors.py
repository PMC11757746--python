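"""Exception hierarchy.

Every error raised by the library derives from :class:`DsirError` so CLI and
pipeline code can catch one base class and report a single-line diagnostic.
"""


class DsirError(Exception):
    """Base class for all dsir errors."""


class ParseError(DsirError):
    """A spectrum or manifest file could not be parsed."""


class ValidationError(DsirError, ValueError):
    """Input data violates a documented invariant."""


class AlignmentError(DsirError):
    """A grid point falls outside the source spectrum's range (no extrapolation)."""


class FormatError(DsirError):
    """A serialized model file is malformed or of unknown version."""


class DegenerateSpectrumError(ValidationError):
    """A constant spectrum row cannot be min-max normalized."""


class EmptyRegionError(ValidationError):
    """A wavenumber region selects zero columns on the bound grid."""


class GridMismatchError(ValidationError):
    """Prediction-time grid is incompatible with the model's training grid."""


class ConfigurationError(DsirError):
    """A cross-validation or sweep configuration is infeasible."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation is undefined (constant reference values)."""


class DivisionDomainError(ValidationError):
    """Mean relative error is undefined when a reference value is zero."""
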