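"""Exception hierarchy shared across the package.

The CLI maps each class to a distinct exit code, so library code should
raise the most specific class that applies.
"""


class LigmigrateError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(LigmigrateError):
    """Invalid or incomplete run configuration."""

    exit_code = 2


class FormatError(LigmigrateError):
    """Unparsable or schema-violating input file."""

    exit_code = 3


class DomainError(LigmigrateError):
    """Operation preconditions violated (geometry, indices, degenerate input)."""

    exit_code = 4


class ProtocolError(LigmigrateError):
    """A multi-stage protocol could not proceed (e.g. no frame survives filters)."""

    exit_code = 5
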