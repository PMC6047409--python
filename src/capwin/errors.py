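"""Exception hierarchy."""


class CapwinError(Exception):
    """Base class for all package errors."""


class ValidationError(CapwinError):
    """Input values violate a documented contract."""


class ParseError(CapwinError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(CapwinError):
    """A tabular input is missing required columns."""
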