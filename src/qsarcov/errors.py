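"""Exception hierarchy shared across the package."""


class QsarcovError(Exception):
    """Base class for all package errors."""


class SchemaError(QsarcovError):
    """An input table is missing required columns or has an unusable layout."""


class ValidationError(QsarcovError):
    """A record or configuration violates a documented invariant."""


class DomainError(QsarcovError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class InsufficientDataError(QsarcovError):
    """Too few observations for the requested statistical operation."""


class DegenerateDataError(QsarcovError):
    """Data with no usable variation (constant column, identical samples)."""
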