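"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class NumericsError(RuntimeError):
    """A numerical routine failed to converge; the message carries diagnostics."""


class SchemaError(ValueError):
    """A serialized file does not match the expected schema or version."""
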