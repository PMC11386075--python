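"""Exception types shared across the package."""


class TowgrowError(Exception):
    """Base class for all package errors."""


class ValidationError(TowgrowError):
    """Input violates a documented precondition or invariant."""


class InsufficientDataError(TowgrowError):
    """Too few usable observations for the requested computation."""


class SchemaError(ValidationError):
    """A delimited-text table does not match its expected schema."""
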