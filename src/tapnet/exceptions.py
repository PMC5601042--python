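"""Exception hierarchy shared across the pipeline."""


class TapnetError(Exception):
    """Base class for all package errors."""


class ParseError(TapnetError, ValueError):
    """A file could not be parsed; the message names the offending line/cell."""


class ValidationError(TapnetError, ValueError):
    """Parsed data violates a domain invariant (bounds, uniqueness, shape)."""


class ConfigurationError(TapnetError, ValueError):
    """A configuration object or design file is inconsistent or incomplete."""


class DomainError(TapnetError, ValueError):
    """An operation was called outside its mathematical domain."""
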