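"""Exception hierarchy shared across the package."""


class TwinclockError(Exception):
    """Base class for all package errors."""


class ConfigError(TwinclockError):
    """Invalid configuration; ``field`` names the offending entry."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class CohortValidationError(TwinclockError):
    """Cohort table violates an invariant; ``row`` is the 1-based CSV row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DegenerateDataError(TwinclockError):
    """Design matrix or input data carries no usable variation."""


class EstimationError(TwinclockError):
    """Model estimation failed; carries optional diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
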