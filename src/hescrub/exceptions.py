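"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a precondition (bad size, range, or combination)."""


class DegenerateInputError(ValueError):
    """The input is structurally unusable (e.g. achromatic image, empty masks)."""
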