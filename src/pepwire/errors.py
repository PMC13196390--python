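"""Exception hierarchy.

Every parser and validator raises a subclass of :class:`PepwireError` with a
message naming the offending location (file, column, feature, node ...) rather
than silently coercing bad input.
"""


class PepwireError(Exception):
    """Base class for all errors raised by pepwire."""


class FormatError(PepwireError):
    """Malformed input file (bad header, bad value, duplicate key ...)."""


class ConfigError(PepwireError):
    """Invalid or unknown configuration key/value."""


class ValidationError(PepwireError):
    """A domain object violates one of its invariants."""
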