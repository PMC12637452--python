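"""Exception types shared across the package."""


class BudcallError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BudcallError, ValueError):
    """A config field or function argument violates its contract."""


class SchemaError(BudcallError, ValueError):
    """A tabular file is missing required columns or has bad values."""


class AlignmentError(BudcallError, ValueError):
    """Predicted and ground-truth cohorts do not share the same cell ids."""


class FormatError(BudcallError, IOError):
    """A file could not be read in the expected format."""
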