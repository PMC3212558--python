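"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""
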