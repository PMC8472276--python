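"""Exception types shared across the package."""


class ChainValidationError(ValueError):
    """A chain or design parameter violates its domain constraints."""


class DegenerateInputError(ValueError):
    """An input is numerically degenerate (e.g. a zero-variance column)."""


class EmptyGroupError(ValueError):
    """A group comparison was requested with an empty group."""
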