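"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition (range, shape, schema)."""


class EstimationError(RuntimeError):
    """A model or matrix cannot be estimated from the data supplied."""
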