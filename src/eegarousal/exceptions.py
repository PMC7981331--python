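"""Exception hierarchy shared across the package."""


class EegArousalError(Exception):
    """Base class for all package errors."""


class FormatError(EegArousalError):
    """A file is missing, truncated, or not in the expected on-disk format."""


class UnsupportedDialectError(FormatError):
    """The file is recognized but uses an encoding this reader does not support."""


class ValidationError(EegArousalError):
    """Input data violates a documented invariant."""


class ConfigError(EegArousalError):
    """A configuration value is out of range or inconsistent."""


class CapabilityError(EegArousalError):
    """The recording lacks a channel required by the requested analysis."""
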