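"""Exception hierarchy shared across the package."""


class SbModelError(Exception):
    """Base class for all package errors."""


class SchemaError(SbModelError):
    """An input file or table does not match the expected schema."""


class ValidationError(SbModelError):
    """A table is schematically valid but violates a domain invariant."""


class DomainError(SbModelError, ValueError):
    """A scalar argument is outside its documented domain."""


class NumericalError(SbModelError):
    """A numerical routine failed to converge or produced invalid output."""
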