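"""Exception hierarchy shared across the pipeline stages."""


class GmscreenError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(GmscreenError, ValueError):
    """An argument or simulation parameter is outside its documented domain."""


class ValidationError(GmscreenError, ValueError):
    """An input record violates a schema or field invariant."""


class PlateQCError(GmscreenError):
    """A plate fails a quality-control precondition (e.g. too few control cells)."""


class SchemaError(GmscreenError, ValueError):
    """A table does not match its declared schema."""
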