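"""Exception types shared across the package."""


class CapacityError(ValueError):
    """More product pools than the model supports (at most four)."""


class SchemaError(ValueError):
    """Input table or configuration violates the expected schema."""


class DegenerateDataError(ValueError):
    """Data carry no usable information (e.g. an all-zero substrate trace)."""
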