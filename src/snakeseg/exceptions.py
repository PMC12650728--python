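"""Shared exception types."""


class ConfigurationError(ValueError):
    """A module was configured inconsistently (channel counts, specs...)."""


class ShapeError(ValueError):
    """Array arguments have incompatible shapes."""
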