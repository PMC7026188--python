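"""Exception hierarchy for the package."""


class AKIAlertError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AKIAlertError):
    """Invalid input data or configuration."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class ReferenceCoverageError(AKIAlertError):
    """An age falls outside the reference table's covered range."""


class DegenerateTableError(AKIAlertError):
    """A contingency table has a zero row or column margin."""
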