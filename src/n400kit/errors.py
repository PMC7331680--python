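"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented invariant (shapes, labels, windows...)."""


class DegenerateNullError(ValueError):
    """A null distribution (or series) has zero variance, so the requested
    statistic is undefined."""
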