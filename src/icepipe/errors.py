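"""Exception hierarchy shared across the pipeline."""


class IcepipeError(Exception):
    """Base class for all package errors."""


class ParseError(IcepipeError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(IcepipeError):
    """Input content violated a documented invariant."""


class ConfigurationError(IcepipeError):
    """A required configuration entry (e.g. an INFO key) is absent or invalid."""
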