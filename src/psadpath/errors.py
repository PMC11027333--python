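"""Exception hierarchy.

Everything user-facing derives from :class:`PsadPathError` so callers (and
the CLI) can distinguish validation problems (exit code 2) from internal
failures (exit code 1).
"""


class PsadPathError(Exception):
    """Base class for all package errors."""


class ValidationError(PsadPathError, ValueError):
    """A value or record violates a domain invariant."""


class SchemaError(ValidationError):
    """A cohort file does not conform to the documented CSV schema."""


class ConfigError(ValidationError):
    """A pathway or run configuration document is invalid."""


class InfeasibleError(PsadPathError):
    """A set of calibration constraints cannot be satisfied."""
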