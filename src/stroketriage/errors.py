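class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class ParseError(ValueError):
    """Raised when an external file (centers CSV, travel-time matrix, config)
    cannot be interpreted; the message names the offending field or path."""
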