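"""Exception types shared across the package.

``ConfigError`` covers invalid parameters (CLI exit code 2), ``DataError``
covers malformed or degenerate input data (CLI exit code 3).
"""


class ConfigError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class DataError(ValueError):
    """Input data are missing, malformed, or degenerate for the requested operation."""
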