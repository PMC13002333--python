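"""Exception hierarchy shared across the package."""


class ModeseekError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ModeseekError, ValueError):
    """Invalid design, observer, or model configuration."""


class ShapeError(ModeseekError, ValueError):
    """Mismatched array or image shapes."""


class CalibrationError(ModeseekError, RuntimeError):
    """Contrast calibration could not reach the requested sensitivity."""


class InsufficientDataError(ModeseekError, ValueError):
    """An operation requires trials or conditions that are absent."""


class UndefinedValueError(ModeseekError, ArithmeticError):
    """A ratio or angle is undefined for the given input (e.g. zero power)."""


class SchemaError(ModeseekError, ValueError):
    """A table does not match the expected column schema."""


class OrderingError(ModeseekError, ValueError):
    """Trial table is not sorted by participant, session, trial."""
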