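"""Exception hierarchy.

Every error raised by the package derives from :class:`GatkinError` so callers
(and the CLI) can map failure categories to exit codes.
"""


class GatkinError(Exception):
    """Base class for all package errors."""


class InputDomainError(GatkinError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ProtocolMismatchError(GatkinError, ValueError):
    """Two recordings that must share a protocol do not; message names the field."""


class FormatError(GatkinError, ValueError):
    """A file does not conform to a canonical format; message names line/column."""


class ConfigError(GatkinError, ValueError):
    """A run configuration failed validation."""
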