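"""Exception hierarchy.

Validation failures (bad values, schema violations) and configuration
problems are kept distinct from ordinary lookup errors so the CLI can map
them onto exit codes.
"""


class ScorecalError(Exception):
    """Base class for all package errors."""


class ValidationError(ScorecalError, ValueError):
    """An input value or table violates a domain invariant."""


class CoverageError(ValidationError, LookupError):
    """A required (sex, age band) entry is missing from a table."""


class ConfigurationError(ScorecalError):
    """A coefficient or run-configuration problem (e.g. unresolvable beta)."""


class IOFormatError(ScorecalError):
    """A file does not conform to the expected schema."""
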