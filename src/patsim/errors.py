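"""Exception hierarchy shared across the package."""


class PatsimError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PatsimError, ValueError):
    """A feature schema is internally inconsistent."""


class ValidationError(PatsimError, ValueError):
    """Data does not conform to its schema (missing cell, unknown level, shape mismatch)."""


class ParameterizationError(PatsimError, ValueError):
    """An operation received parameters outside its documented domain."""


class DomainError(PatsimError, ValueError):
    """A value is outside the mathematical domain of a derivation rule."""
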