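"""Exception hierarchy shared across the package."""


class DlonmfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DlonmfError, ValueError):
    """Input data violates a structural invariant (duplicates, NaN, shape)."""


class FormatError(DlonmfError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ParseError(FormatError):
    """A cell could not be parsed; carries row/column coordinates in the message."""


class NonNegativityError(ValidationError):
    """Negative entries found where a non-negative matrix is required."""


class ParameterError(DlonmfError, ValueError):
    """A hyperparameter or call argument is out of its admissible range."""


class ShapeError(DlonmfError, ValueError):
    """Operand dimensions are incompatible."""


class NumericalError(DlonmfError, ArithmeticError):
    """A non-finite value appeared during iteration."""


class UndefinedMetricError(DlonmfError, ValueError):
    """A metric is undefined for the given input (e.g. constant matrix, one cluster)."""
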