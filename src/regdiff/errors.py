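"""Exception hierarchy shared across the package.

Input errors (malformed or inconsistent data) and config errors
(invalid parameter choices) are distinguished so the CLI can map them
to distinct exit codes.
"""


class RegdiffError(Exception):
    """Base class for all package errors."""


class InputError(RegdiffError):
    """Malformed or internally inconsistent input data."""


class ParseError(InputError):
    """A file could not be parsed; message names the offending location."""


class ConfigError(RegdiffError):
    """Invalid parameter or configuration value."""
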