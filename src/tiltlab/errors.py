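"""Shared exception types."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract (invalid parameters,
    malformed trial tables, unknown tokens, unbalanced designs, ...)."""
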