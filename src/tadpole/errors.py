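"""Exception hierarchy shared across the package."""


class TadpoleError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(TadpoleError):
    """Input file does not encode a square numeric matrix."""


class MatrixValidationError(TadpoleError):
    """Matrix content violates a contract (asymmetry, negativity, ...)."""


class ParameterError(TadpoleError, ValueError):
    """A numeric or structural parameter is outside its documented range."""


class UndefinedMetricError(TadpoleError):
    """The requested quantity is mathematically undefined for this input."""
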