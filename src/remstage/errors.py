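"""Exception hierarchy.

``ConfigError`` covers bad parameters and malformed configuration,
``DataError`` covers problems with input signals or annotation files.
The CLI maps these onto distinct exit codes.
"""


class RemstageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RemstageError):
    """Invalid parameter, option or configuration value."""


class DataError(RemstageError):
    """Invalid or inconsistent input data."""


class ChannelNotFoundError(DataError):
    """Requested EDF channel is absent; message lists available labels."""


class DialectError(DataError):
    """Hypnogram token not covered by the dialect's mapping table."""
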