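"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError (including
ParseError) -> 3, anything else -> 4.
"""


class SkipticsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SkipticsError):
    """Invalid run configuration (missing paths, out-of-range thresholds)."""


class DataError(SkipticsError):
    """Input data violates a documented contract."""


class ParseError(DataError):
    """A file could not be parsed; the message names the file and line."""
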