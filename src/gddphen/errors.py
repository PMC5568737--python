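"""Exception hierarchy shared across the package."""


class GddphenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GddphenError):
    """A file does not conform to the expected tabular layout."""


class RowError(GddphenError):
    """One or more data rows are invalid; carries line numbers."""

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class ConfigurationError(GddphenError):
    """A configuration value is missing or inconsistent."""


class InputError(GddphenError):
    """An argument violates an operation's precondition."""


class DataCompletenessError(GddphenError):
    """Required companion data (e.g. a temperature series) is missing."""

    def __init__(self, message: str, missing: list | None = None):
        super().__init__(message)
        self.missing = missing or []


class InsufficientDataError(GddphenError):
    """Fewer calibration records than the minimum sample size."""


class UndefinedMetricError(GddphenError):
    """A metric's denominator or variance is zero; the value is undefined."""


class AlignmentError(GddphenError):
    """Two grids that must share shape/georeferencing do not."""


class EmptyEnvelopeError(GddphenError):
    """No calibration point yielded a usable spring-temperature value."""
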