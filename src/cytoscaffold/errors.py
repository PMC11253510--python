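"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError (and
subclasses) -> 3, anything else -> 4.
"""


class CytoscaffoldError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CytoscaffoldError):
    """Invalid configuration (bad parameter value, malformed config file)."""


class DataError(CytoscaffoldError):
    """Invalid or degenerate input data."""


class FormatError(DataError):
    """A file could not be parsed under its declared format."""


class ValidationError(DataError):
    """Parsed data violates a structural invariant (duplicates, NaNs, ...)."""
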