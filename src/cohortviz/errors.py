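"""Exception hierarchy shared across the pipeline."""


class CohortVizError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CohortVizError):
    """Malformed table structure (duplicate headers, ragged rows)."""


class LoadError(CohortVizError):
    """A required input file is missing or unreadable."""


class DateParseError(CohortVizError):
    """A date cell does not follow the ISO YYYY-MM-DD dialect."""


class ConfigError(CohortVizError):
    """A specification value is missing, malformed or out of its enumeration."""


class ExpressionError(ConfigError):
    """Syntax or vocabulary error in the subset/indicator mini-language."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)
        self.position = position


class EvaluationError(CohortVizError):
    """A predicate references a column absent from the table it runs on."""


class DataError(CohortVizError):
    """Inconsistent cohort content (e.g. end date before start date)."""


class DomainError(CohortVizError):
    """A value transform was applied outside its mathematical domain."""
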