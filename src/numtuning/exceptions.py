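"""Package-specific error types.

All inherit from ``ValueError`` so callers that do not care about the
distinction can catch a single base class.
"""


class NumtuningError(ValueError):
    """Base class for all errors raised by this package."""


class DomainError(NumtuningError):
    """A numeric argument is outside its mathematical domain (e.g. w <= 0)."""


class ValidationError(NumtuningError):
    """Input data violate a structural contract (labels, shapes, ranges)."""


class InsufficientDataError(NumtuningError):
    """Too few observations to carry out the requested estimate."""


class SchemaError(NumtuningError):
    """A configuration file contains an unknown or invalid key."""

    def __init__(self, key: str, message: str | None = None):
        self.key = key
        super().__init__(message or f"invalid configuration key: {key!r}")
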